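"""Paired SDOCT-SAP test records: data model, QC, splitting, and I/O.

A record pairs one peripapillary RNFL thickness scan (768 samples, TSNIT
order, on the 3.45 mm circle) with one 24-2 visual-field test (52 total
deviation values in canonical grid order, plus the MD summary), carried out
within 180 days of each other, together with the reliability metadata used
for quality control.

On disk a dataset is one row per record with columns::

    patient_id, eye, age, sap_date, oct_date, fixation_loss_pct,
    false_positive_pct, quality_score, md, split, td_0..td_51, rnfl_0..rnfl_767

as CSV, or an HDF5 container with datasets ``rnfl`` (N x 768), ``td``
(N x 52) and one dataset per metadata column under ``meta/``.

Both eyes are stored in the eye-local, temporal-positive convention: the
TSNIT scan order and the chart's blind-spot side are defined relative to
each eye's own temporal pole, so left and right eyes share one layout (the
24-2 chart is not symmetric in x, which rules out a within-chart mirror).
Display-convention left-eye exports must be mirrored into this convention
before a Dataset is constructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .vf_geometry import interval_of

logger = logging.getLogger(__name__)

__all__ = [
    "RNFLProfile",
    "PairedTest",
    "Dataset",
    "QC_RULES",
    "qc_filter",
    "split_by_patient",
    "split_rnfl",
    "read_dataset",
    "write_dataset",
]

META_COLUMNS = [
    "patient_id", "eye", "age", "sap_date", "oct_date",
    "fixation_loss_pct", "false_positive_pct", "quality_score", "md", "split",
]
TD_COLUMNS = [f"td_{j}" for j in range(52)]
RNFL_COLUMNS = [f"rnfl_{k}" for k in range(768)]

#: QC exclusion rules, applied strictly as printed (boundary values pass).
QC_RULES = {
    "fixation_loss": "fixation_loss_pct > 33",
    "false_positive": "false_positive_pct > 15",
    "quality": "quality_score < 15",
    "pairing_window": "|sap_date - oct_date| > 180 days",
}


@dataclass
class RNFLProfile:
    """A 768-sample TSNIT thickness profile (micrometres) plus scan quality."""

    thickness: np.ndarray
    quality_score: float = np.nan

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (768,):
            raise ValueError(f"thickness must have shape (768,), got {self.thickness.shape}")
        if not np.all(np.isfinite(self.thickness)) or np.any(self.thickness < 0):
            raise ValueError("thickness values must be finite and non-negative")


def split_rnfl(profile: "RNFLProfile | np.ndarray", start_offset: int = 0
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Split a TSNIT profile into its superior and inferior hemiretina halves.

    With the default offset, samples 0..383 (temporal through superior into
    nasal) form the superior half and 384..767 the inferior half;
    ``start_offset`` rotates the split point for scans that do not start
    exactly at the temporal pole.  Concatenating the halves (after undoing
    the rotation) reproduces the input.
    """
    x = profile.thickness if isinstance(profile, RNFLProfile) else np.asarray(profile, float)
    if x.shape != (768,):
        raise ValueError(f"expected 768 samples, got {x.shape}")
    if start_offset:
        x = np.roll(x, -start_offset)
    return x[:384].copy(), x[384:].copy()


@dataclass
class PairedTest:
    """One quality-annotated SDOCT-SAP pair."""

    patient_id: str
    eye: str
    age: float
    sap_date: date
    oct_date: date
    td: np.ndarray
    md: float
    fixation_loss_pct: float
    false_positive_pct: float
    rnfl: RNFLProfile
    split: str = ""

    def __post_init__(self):
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        self.td = np.asarray(self.td, dtype=float)
        if self.td.shape != (52,):
            raise ValueError(f"td must have shape (52,), got {self.td.shape}")

    @property
    def pairing_gap_days(self) -> int:
        return abs((self.sap_date - self.oct_date).days)


class Dataset:
    """A collection of paired tests stored column-wise in a DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in META_COLUMNS[:-1] + TD_COLUMNS + RNFL_COLUMNS
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        frame = frame.copy()
        if "split" not in frame.columns:
            frame["split"] = ""
        self.frame = frame.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PairedTest]) -> "Dataset":
        rows = []
        for r in records:
            row = {
                "patient_id": r.patient_id, "eye": r.eye, "age": r.age,
                "sap_date": r.sap_date.isoformat(), "oct_date": r.oct_date.isoformat(),
                "fixation_loss_pct": r.fixation_loss_pct,
                "false_positive_pct": r.false_positive_pct,
                "quality_score": r.rnfl.quality_score, "md": r.md, "split": r.split,
            }
            row.update({c: v for c, v in zip(TD_COLUMNS, r.td)})
            row.update({c: v for c, v in zip(RNFL_COLUMNS, r.rnfl.thickness)})
            rows.append(row)
        return cls(pd.DataFrame(rows))

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def rnfl(self) -> np.ndarray:
        """(N, 768) thickness matrix."""
        return self.frame[RNFL_COLUMNS].to_numpy(float)

    @property
    def td(self) -> np.ndarray:
        """(N, 52) total-deviation matrix, canonical order."""
        return self.frame[TD_COLUMNS].to_numpy(float)

    @property
    def md(self) -> np.ndarray:
        return self.frame["md"].to_numpy(float)

    @property
    def splits(self) -> pd.Series:
        return self.frame["split"]

    def interval_counts(self) -> Dict[int, int]:
        """Record counts N_1..N_4 of the four MD intervals."""
        ids = [interval_of(m) for m in self.md]
        return {i: ids.count(i) for i in (1, 2, 3, 4)}

    def subset(self, split: str) -> "Dataset":
        return Dataset(self.frame[self.frame["split"] == split])

    def records(self) -> List[PairedTest]:
        out = []
        for _, row in self.frame.iterrows():
            out.append(PairedTest(
                patient_id=str(row["patient_id"]), eye=row["eye"], age=float(row["age"]),
                sap_date=date.fromisoformat(str(row["sap_date"])),
                oct_date=date.fromisoformat(str(row["oct_date"])),
                td=row[TD_COLUMNS].to_numpy(float), md=float(row["md"]),
                fixation_loss_pct=float(row["fixation_loss_pct"]),
                false_positive_pct=float(row["false_positive_pct"]),
                rnfl=RNFLProfile(row[RNFL_COLUMNS].to_numpy(float),
                                 quality_score=float(row["quality_score"])),
                split=str(row["split"]),
            ))
        return out

    def equals(self, other: "Dataset") -> bool:
        a = self.frame[META_COLUMNS + TD_COLUMNS + RNFL_COLUMNS]
        b = other.frame[META_COLUMNS + TD_COLUMNS + RNFL_COLUMNS]
        if len(a) != len(b):
            return False
        num = TD_COLUMNS + RNFL_COLUMNS + ["age", "md", "fixation_loss_pct",
                                           "false_positive_pct", "quality_score"]
        return (
            bool(np.allclose(a[num].to_numpy(float), b[num].to_numpy(float),
                             rtol=0, atol=1e-9))
            and a[["patient_id", "eye", "sap_date", "oct_date", "split"]].astype(str)
            .equals(b[["patient_id", "eye", "sap_date", "oct_date", "split"]].astype(str))
        )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(dataset: Dataset) -> Tuple[Dataset, pd.DataFrame]:
    """Apply the reliability and pairing-window exclusions.

    Returns the retained dataset and a frame of dropped rows with a
    ``qc_reason`` column naming the first triggered rule.  Rows with missing
    QC metadata are dropped with reason ``missing_metadata`` (logged).
    Thresholds are strict, so boundary values (33 % fixation losses, 15 %
    false positives, quality 15, 180-day gap) are retained.
    """
    df = dataset.frame
    fl = pd.to_numeric(df["fixation_loss_pct"], errors="coerce")
    fp = pd.to_numeric(df["false_positive_pct"], errors="coerce")
    q = pd.to_numeric(df["quality_score"], errors="coerce")
    gap = (pd.to_datetime(df["sap_date"]) - pd.to_datetime(df["oct_date"])).abs().dt.days

    reason = pd.Series("", index=df.index, dtype=object)
    missing = fl.isna() | fp.isna() | q.isna() | gap.isna()
    reason[missing] = "missing_metadata"
    reason[(reason == "") & (fl > 33)] = "fixation_loss"
    reason[(reason == "") & (fp > 15)] = "false_positive"
    reason[(reason == "") & (q < 15)] = "quality"
    reason[(reason == "") & (gap > 180)] = "pairing_window"

    if missing.any():
        logger.warning("qc_filter: %d record(s) dropped for missing QC metadata",
                       int(missing.sum()))
    dropped = df[reason != ""].copy()
    dropped["qc_reason"] = reason[reason != ""]
    return Dataset(df[reason == ""]), dropped


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------

def split_by_patient(dataset: Dataset,
                     fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> Dataset:
    """Assign train/val/test split labels at the patient level.

    All records of a patient share one label.  Patients are shuffled under
    ``seed`` and assigned greedily: each patient goes to the split whose
    realized record fraction is currently furthest below its target, so the
    record-level fractions track the requested ones.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    df = dataset.frame
    patients = df["patient_id"].astype(str).unique()
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    counts = df.groupby(df["patient_id"].astype(str)).size()
    total = float(len(df))
    names = ("train", "val", "test")
    assigned = {s: 0.0 for s in names}
    label: Dict[str, str] = {}
    for idx in order:
        pid = patients[idx]
        deficits = [fractions[i] - assigned[s] / total for i, s in enumerate(names)]
        best = names[int(np.argmax(deficits))]
        label[pid] = best
        assigned[best] += counts[pid]
    out = df.copy()
    out["split"] = df["patient_id"].astype(str).map(label)
    return Dataset(out)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path: str) -> None:
    """Write a dataset as CSV or (for .h5/.hdf5 paths) HDF5."""
    cols = META_COLUMNS + TD_COLUMNS + RNFL_COLUMNS
    df = dataset.frame[cols]
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("rnfl", data=df[RNFL_COLUMNS].to_numpy(float))
            f.create_dataset("td", data=df[TD_COLUMNS].to_numpy(float))
            meta = f.create_group("meta")
            for c in META_COLUMNS:
                vals = df[c].to_numpy()
                if vals.dtype == object or str(vals.dtype).startswith("str"):
                    meta.create_dataset(c, data=np.array([str(v) for v in vals], dtype="S"))
                else:
                    meta.create_dataset(c, data=vals)
    else:
        df.to_csv(path, index=False)


def read_dataset(path: str) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Malformed rows raise with row numbers; an empty file yields an empty
    dataset with a logged warning.
    """
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            rnfl = f["rnfl"][()]
            td = f["td"][()]
            meta = {c: f["meta"][c][()] for c in f["meta"]}
        df = pd.concat([
            pd.DataFrame({c: (np.char.decode(v.astype("S"), "utf-8")
                              if v.dtype.kind == "S" else v)
                          for c, v in meta.items()}),
            pd.DataFrame(td, columns=TD_COLUMNS),
            pd.DataFrame(rnfl, columns=RNFL_COLUMNS),
        ], axis=1)
    else:
        df = pd.read_csv(path, dtype={"patient_id": str})
    if len(df) == 0:
        logger.warning("read_dataset: %s is empty", path)
        df = pd.DataFrame(columns=META_COLUMNS + TD_COLUMNS + RNFL_COLUMNS)
        return Dataset(df)
    missing = [c for c in META_COLUMNS[:-1] + TD_COLUMNS + RNFL_COLUMNS
               if c not in df.columns]
    if missing:
        raise ValueError(f"dataset at {path} is missing columns: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    vec = df[TD_COLUMNS + RNFL_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = vec.isna().any(axis=1)
    if bad.any():
        rows = list(df.index[bad][:10])
        raise ValueError(f"malformed numeric values in rows {rows}")
    return Dataset(df)
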