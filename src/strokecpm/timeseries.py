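"""Per-subject ROI time-series container and its delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectTimeseries", "read_timeseries", "write_timeseries"]

#: column order of the nuisance design: six rigid-body motion parameters
#: followed by global-mean, white-matter and CSF signal proxies.
NUISANCE_NAMES = [
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "global", "white_matter", "csf",
]


@dataclass
class SubjectTimeseries:
    """BOLD-like ROI signals (T x M) plus a nuisance design (T x K).

    The nuisance block holds the six head-motion parameters and the
    global/white-matter/CSF mean-signal proxies (K = 9 by convention, but
    any K >= 1 is accepted).
    """

    subject_id: str
    data: np.ndarray
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x M matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain non-finite values")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.ndim != 2 or self.nuisance.shape[0] != self.data.shape[0]:
                raise ValueError("nuisance must have the same number of rows as data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "SubjectTimeseries":
        return SubjectTimeseries(self.subject_id, data, self.nuisance)


def write_timeseries(ts: SubjectTimeseries, path: str | Path,
                     labels: list[str] | None = None) -> None:
    """Write T rows x M node columns as tab-delimited text with a header."""
    if labels is None:
        labels = [f"node_{j:03d}" for j in range(ts.n_nodes)]
    pd.DataFrame(ts.data, columns=labels).to_csv(path, sep="\t", index=False,
                                                 float_format="%.8g")


def read_timeseries(path: str | Path, subject_id: str | None = None) -> SubjectTimeseries:
    """Read a delimited time-series table (header row of node labels)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if subject_id is None:
        subject_id = Path(path).stem
    return SubjectTimeseries(subject_id=subject_id, data=df.to_numpy(dtype=float))
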