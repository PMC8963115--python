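scene_id,background,movement_class,components,acceleration_rate,translation_speed,fov_deg,frame_reference,duration_s,duration_measured,controllable,category
S001,urban,complex,tf;rr;ry,,moderate_4mps,90,no,14.6,yes,yes,CCU
S002,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,14.9,yes,yes,CCU
S003,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,14.8,yes,yes,CCU
S004,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,14.2,yes,yes,CCU
S005,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,15.6,yes,yes,CCU
S006,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,15.2,yes,yes,CCU
S007,urban,complex,tf;rr;ry,,moderate_4mps,90,no,28.0,yes,yes,CCU
S008,urban,complex,tf;rr;ry,,moderate_4mps,90,no,27.5,yes,yes,CCU
S101,astrospace,simple,ry,,none,90,no,13,no,no,CUA
S102,astrospace,simple,rr,,none,90,no,13,no,no,CUA
S103,astrospace,simple,rp,,none,90,no,13,no,no,CUA
S104,astrospace,simple,tf,,moderate_4mps,90,no,13,no,no,CUA
S105,astrospace,simple,tb,,moderate_4mps,90,no,13,no,no,CUA
S106,astrospace,simple,tl,,moderate_4mps,90,no,13,no,no,CUA
S107,astrospace,simple,tu,,moderate_4mps,90,no,13,no,no,CUA
S108,astrospace,simple,td,,moderate_4mps,90,no,13,no,no,CUA
S109,astrospace,complex,tf;tu;td;rp,,moderate_4mps,90,no,13,no,no,CUA
S110,astrospace,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUA
S111,astrospace,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,13,no,no,CUA
S112,astrospace,complex,tf;rr;ry,,fast_9.2mps,90,no,13,no,no,CUA
S113,astrospace,complex,tf;tu;td;rr;ry;rp,,fast_9.2mps,90,no,13,no,no,CUA
S114,astrospace,complex,tf;rr;ry,,moderate_4mps,45,no,13,no,no,CUA
S115,astrospace,complex,tf;rr;ry,,moderate_4mps,30,no,13,no,no,CUA
S116,astrospace,complex,tf;rr;ry,1.60,moderate_4mps,90,no,13,no,no,CUA
S117,astrospace,complex,tf;tu;td;rr;ry;rp,1.60,moderate_4mps,90,no,13,no,no,CUA
S118,astrospace,complex,tf;tu;td;rr;ry;rp,1.60,moderate_4mps,90,yes,13,no,no,CUA
S201,urban,simple,ry,,none,90,no,13,no,no,CUU
S202,urban,simple,rr,,none,90,no,13,no,no,CUU
S203,urban,simple,rp,,none,90,no,13,no,no,CUU
S204,urban,simple,tf,,moderate_4mps,90,no,13,no,no,CUU
S205,urban,simple,tb,,moderate_4mps,90,no,13,no,no,CUU
S206,urban,simple,tl,,moderate_4mps,90,no,13,no,no,CUU
S207,urban,simple,tu,,moderate_4mps,90,no,13,no,no,CUU
S208,urban,simple,td,,moderate_4mps,90,no,13,no,no,CUU
S209,urban,complex,tf;tu;td;rp,,moderate_4mps,90,no,13,no,no,CUU
S210,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S211,urban,complex,tf;tu;td;rr;ry;rp,,moderate_4mps,90,no,13,no,no,CUU
S212,urban,complex,tf;rr;ry,,fast_9.2mps,90,no,13,no,no,CUU
S213,urban,complex,tf;tu;td;rr;ry;rp,,fast_9.2mps,90,no,13,no,no,CUU
S214,urban,complex,tf;rr;ry,,moderate_4mps,45,no,13,no,no,CUU
S215,urban,complex,tf;rr;ry,,moderate_4mps,30,no,13,no,no,CUU
S216,urban,complex,tf;rr;ry,1.60,moderate_4mps,90,no,13,no,no,CUU
S217,urban,complex,tf;tu;td;rr;ry;rp,1.60,moderate_4mps,90,no,13,no,no,CUU
S218,urban,complex,tf;tu;td;rr;ry;rp,1.60,moderate_4mps,90,yes,13,no,no,CUU
S219,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S220,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S221,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S222,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S223,urban,complex,tf;rr;ry,,moderate_4mps,90,no,13,no,no,CUU
S224,urban,complex,tf;rr;ry,,moderate_4mps,90,no,24,no,no,CUU
S225,urban,complex,tf;rr;ry,,moderate_4mps,90,no,24,no,no,CUU
S226,urban,complex,tf;rr;ry,1.60,moderate_4mps,90,no,24,no,no,CUU
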