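"""Plain-text readers/writers for study artifacts.

Signal files are CSV with a one-line ``fs=<rate>`` header followed by a
channel-name row and one sample per line.  Score matrices are wide CSV
(participant rows x scene columns); panels, questionnaire responses and
trial boundary tables are tidy CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biosignals import SignalEpoch
from .synthetic import ParticipantProfile

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_scores_csv",
    "read_scores_csv",
    "panel_to_frame",
    "panel_from_frame",
]


def write_signal_csv(path, epoch: SignalEpoch) -> None:
    with open(path, "w") as fh:
        fh.write(f"fs={epoch.fs:g}\n")
        names = epoch.channel_names or tuple(
            f"ch{i}" for i in range(epoch.n_channels)
        )
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, epoch.samples.T, delimiter=",", fmt="%.6g")


def read_signal_csv(path) -> SignalEpoch:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ValueError("signal file must start with an 'fs=<rate>' line")
        fs = float(header[3:])
        names = tuple(fh.readline().strip().split(","))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return SignalEpoch(data.T, fs, names)


def write_scores_csv(path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, index_label="participant_id")


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="participant_id")
    df.columns.name = "scene_id"
    return df


def panel_to_frame(panel) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant_id": p.participant_id, "sex": p.sex,
          "age_years": p.age_years, "group": p.group,
          "mssq_a": p.mssq_a, "mssq_b": p.mssq_b} for p in panel]
    )


def panel_from_frame(df: pd.DataFrame) -> list:
    return [
        ParticipantProfile(r.participant_id, r.sex, int(r.age_years),
                           float(r.mssq_a), float(r.mssq_b))
        for r in df.itertuples()
    ]
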