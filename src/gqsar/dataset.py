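"""Congeneric series handling: activities, splits, filtering, scaling.

The series table format is tab-delimited text with a header row::

    id   R1   R2  ...  R6   pIC50

where each R column carries a substituent SMILES with one ``[*]`` attachment
dummy (or the reserved ``[H]`` token) and pIC50 = −log10(IC50 in molar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import Substituent, parse_substituent
from .errors import ConfigError, DataError


@dataclass(frozen=True)
class SeriesCompound:
    """One member of a congeneric series."""

    id: str
    assignment: dict[str, Substituent]
    pic50: float

    def __post_init__(self):
        if not math.isfinite(self.pic50):
            raise DataError(f"compound {self.id!r}: pIC50 must be finite")


def pic50_from_ic50(ic50_molar: float) -> float:
    """pIC50 = −log10(IC50 in molar units)."""
    if ic50_molar <= 0:
        raise DataError("IC50 must be positive")
    return -math.log10(ic50_molar)


def read_series_table(path, sites: tuple[str, ...] | None = None) -> list[SeriesCompound]:
    """Read a series table; site columns are all columns between id and pIC50."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise DataError(f"cannot read series table {path}: {exc}") from exc
    if "id" not in df.columns or "pIC50" not in df.columns:
        raise DataError(f"series table {path} must have 'id' and 'pIC50' columns")
    site_cols = sites or tuple(c for c in df.columns if c not in ("id", "pIC50"))
    compounds = []
    seen = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        cid = str(row["id"])
        if cid in seen:
            raise DataError(f"{path} line {lineno}: duplicate compound id {cid!r}")
        seen.add(cid)
        try:
            pic50 = float(row["pIC50"])
            assignment = {s: parse_substituent(str(row[s]), s) for s in site_cols}
            compounds.append(SeriesCompound(id=cid, assignment=assignment, pic50=pic50))
        except (ValueError, KeyError, DataError, Exception) as exc:
            raise DataError(f"{path} line {lineno} (compound {cid!r}): {exc}") from exc
    return compounds


def write_series_table(compounds, path, sites: tuple[str, ...] | None = None) -> None:
    if not compounds:
        raise DataError("empty series")
    sites = sites or tuple(compounds[0].assignment)
    rows = []
    for c in compounds:
        row = {"id": c.id}
        row.update({s: c.assignment[s].smiles for s in sites})
        row["pIC50"] = f"{c.pic50:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SplitSpec:
    """Training/test partition: seeded random fraction or explicit test IDs."""

    mode: str = "random"            # "random" | "explicit"
    training_fraction: float = 0.8  # random mode
    test_ids: tuple[str, ...] = ()  # explicit mode
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random", "explicit"):
            raise ConfigError(f"unknown split mode {self.mode!r}")
        if self.mode == "random" and not 0 < self.training_fraction <= 1:
            raise ConfigError("training_fraction must be in (0, 1]")


def split(series: list[SeriesCompound], spec: SplitSpec):
    """Disjoint, exhaustive training/test partition of the series.

    Random mode is deterministic for a fixed seed; explicit mode reproduces a
    named test-ID list.  Series order is preserved within each part.
    """
    ids = [c.id for c in series]
    if spec.mode == "explicit":
        unknown = [t for t in spec.test_ids if t not in ids]
        if unknown:
            raise DataError(f"unknown test ids: {unknown}")
        test_set = set(spec.test_ids)
    else:
        n_train = int(round(spec.training_fraction * len(series)))
        if n_train < 2:
            raise ConfigError("training fraction leaves fewer than 2 training compounds")
        rng = np.random.default_rng(spec.seed)
        test_idx = set(rng.permutation(len(series))[n_train:].tolist())
        test_set = {ids[i] for i in test_idx}
    train = [c for c in series if c.id not in test_set]
    test = [c for c in series if c.id in test_set]
    if len(train) < 2:
        raise ConfigError("split leaves fewer than 2 training compounds")
    return train, test


@dataclass(frozen=True)
class UnicolumnStats:
    """Per-set activity summary (mean/max/min/sample SD/sum), pIC50 units."""

    average: float
    max: float
    min: float
    std_dev: float
    sum: float
    n: int


def unicolumn(values) -> UnicolumnStats:
    """The five unicolumn statistics of an activity column (sample SD, n−1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DataError("unicolumn statistics need at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return UnicolumnStats(average=float(arr.mean()), max=float(arr.max()),
                          min=float(arr.min()), std_dev=sd,
                          sum=float(arr.sum()), n=int(arr.size))


def interpolation_check(train: UnicolumnStats, test: UnicolumnStats):
    """Is the test set interpolative within the training activity range?

    True iff test.min ≥ train.min and test.max ≤ train.max (boundary equality
    allowed).  Returns the verdict and a one-line report.
    """
    ok = test.min >= train.min and test.max <= train.max
    report = (
        f"train range [{train.min:.4f}, {train.max:.4f}], "
        f"test range [{test.min:.4f}, {test.max:.4f}]: "
        + ("test set is interpolative" if ok else "test set extrapolates the training range")
    )
    return ok, report


def remove_invariable(m: pd.DataFrame, variance_cutoff: float = 0.1):
    """Drop constant columns and columns with raw variance below the cutoff.

    Variance is sample variance of the raw (pre-scaling) descriptor values.
    Returns the filtered matrix and the list of dropped column names.
    """
    if variance_cutoff < 0:
        raise ConfigError("variance cutoff must be >= 0")
    variances = m.var(axis=0, ddof=1)
    nunique = m.nunique(axis=0)
    drop = [c for c in m.columns if nunique[c] <= 1 or variances[c] < variance_cutoff]
    kept = m.drop(columns=drop)
    if kept.shape[1] == 0:
        raise DataError(
            f"all {m.shape[1]} descriptor columns removed at variance cutoff "
            f"{variance_cutoff}; lower the cutoff"
        )
    return kept, drop


def autoscale(m: pd.DataFrame):
    """Autoscale each column to mean 0, sample SD 1.

    Returns the scaled matrix plus the per-column (mean, sd) needed to
    back-transform model coefficients to original descriptor units.
    """
    means = m.mean(axis=0)
    sds = m.std(axis=0, ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise DataError(f"constant columns must be removed before autoscaling: {zero}")
    return (m - means) / sds, means, sds
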