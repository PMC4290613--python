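"""Combinatorial R-group library enumeration, prediction and screening.

The library is the full Cartesian product of per-site substituent pools
(optionally with some sites held fixed).  Each enumerated assignment gets a
fragment-descriptor vector, a predicted pIC50 from a fitted model and an
extrapolation score — the maximum range-normalised distance of any model
descriptor outside its training [min, max] (zero means the entry sits fully
inside the model's applicability range).  Entries are ranked by descending
predicted activity, ties broken by ascending extrapolation then by
lexicographic assignment.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator

import pandas as pd

from .chemistry import ScaffoldTemplate, Substituent, assemble
from .descriptors import column_name, split_column_name, substituent_descriptors
from .errors import DataError
from .modeling import FittedModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstituentPool:
    """Candidate substituents for one site."""

    site_label: str
    members: tuple[Substituent, ...]

    def __post_init__(self):
        if not self.members:
            raise DataError(f"pool for {self.site_label} is empty")
        smiles = [m.smiles for m in self.members]
        if len(set(smiles)) != len(smiles):
            raise DataError(f"pool for {self.site_label} has duplicate members")
        bad = [m for m in self.members if m.site_label != self.site_label]
        if bad:
            raise DataError(f"pool member bound to a different site: {bad[0]}")


@dataclass(frozen=True)
class LibraryEntry:
    """One enumerated combination with its prediction."""

    assignment: dict[str, Substituent]
    descriptors: dict[str, float]
    predicted_pic50: float
    extrapolation: float

    def assignment_key(self) -> tuple[str, ...]:
        return tuple(self.assignment[s].smiles for s in sorted(self.assignment))


def enumerate_assignments(pools: Iterable[SubstituentPool],
                          fixed_sites: dict[str, Substituent] | None = None,
                          ) -> Iterator[dict[str, Substituent]]:
    """Stream the full Cartesian product of the pools, lexicographically.

    Sites are visited in sorted label order and members in sorted canonical
    SMILES order, so enumeration is deterministic.  ``fixed_sites`` entries
    are merged into every assignment and must not overlap the pool sites.
    """
    pools = list(pools)
    fixed_sites = dict(fixed_sites or {})
    pool_sites = [p.site_label for p in pools]
    if len(set(pool_sites)) != len(pool_sites):
        raise DataError("duplicate pool site labels")
    overlap = set(pool_sites) & set(fixed_sites)
    if overlap:
        raise DataError(f"sites both pooled and fixed: {sorted(overlap)}")
    if not pools:
        raise DataError("at least one pool is required")
    ordered = sorted(pools, key=lambda p: p.site_label)
    member_lists = [sorted(p.members, key=lambda m: m.smiles) for p in ordered]
    for combo in product(*member_lists):
        assignment = dict(fixed_sites)
        assignment.update({p.site_label: m for p, m in zip(ordered, combo)})
        yield assignment


def library_size(pools: Iterable[SubstituentPool]) -> int:
    size = 1
    for p in pools:
        size *= len(p.members)
    return size


def extrapolation_score(d: dict[str, float], model: FittedModel) -> float:
    """Max range-normalised distance of any model descriptor outside training.

    0 inside every training [min, max]; a descriptor at max + 0.5×range
    scores 0.5.  A zero-width training range contributes 0 when the value
    equals it and ``inf`` otherwise.
    """
    worst = 0.0
    for name in model.descriptor_names:
        if name not in d:
            raise DataError(f"descriptor vector is missing {name!r}")
        lo, hi = model.training_ranges[name]
        x = float(d[name])
        if lo <= x <= hi:
            continue
        width = hi - lo
        if width == 0:
            return math.inf
        dist = (lo - x) if x < lo else (x - hi)
        worst = max(worst, dist / width)
    return worst


def _entry_descriptors(assignment: dict[str, Substituent], sites: list[str],
                       cache: dict, acceptor_rule: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for site in sites:
        sub = assignment[site]
        key = (site, sub.smiles)
        if key not in cache:
            cache[key] = {
                column_name(site, n): v
                for n, v in substituent_descriptors(sub, acceptor_rule).items()
            }
        out.update(cache[key])
    return out


def score_library(assignments: Iterable[dict[str, Substituent]], model: FittedModel,
                  top_k: int | None = None, max_extrapolation: float | None = None,
                  acceptor_rule: str = "NO") -> list[LibraryEntry]:
    """Predict and rank enumerated assignments with a fitted model.

    Streaming: with ``top_k`` only the current best k entries are buffered.
    Entries whose descriptors cannot be computed are skipped with a logged
    reason, never silently.  Ranking: descending predicted pIC50, then
    ascending extrapolation, then lexicographic assignment.
    """
    model_sites = sorted({split_column_name(n)[0] for n in model.descriptor_names})
    cache: dict = {}

    def generate() -> Iterator[LibraryEntry]:
        for assignment in assignments:
            missing = [s for s in model_sites if s not in assignment]
            if missing:
                raise DataError(f"assignment lacks model sites {missing}")
            try:
                desc = _entry_descriptors(assignment, model_sites, cache, acceptor_rule)
                pred, _ = model.predict_one(desc)
                extra = extrapolation_score(desc, model)
            except DataError:
                raise
            except Exception as exc:
                key = {s: a.smiles for s, a in assignment.items()}
                logger.warning("skipping library entry %s: %s", key, exc)
                continue
            if max_extrapolation is not None and extra > max_extrapolation:
                continue
            yield LibraryEntry(assignment=dict(assignment), descriptors=desc,
                               predicted_pic50=pred, extrapolation=extra)

    def rank_key(e: LibraryEntry):
        return (-e.predicted_pic50, e.extrapolation, e.assignment_key())

    if top_k is not None:
        return heapq.nsmallest(top_k, generate(), key=rank_key)
    return sorted(generate(), key=rank_key)


def entries_to_dataframe(entries: list[LibraryEntry]) -> pd.DataFrame:
    """Flatten ranked entries into a table (one SMILES column per site)."""
    rows = []
    for rank, e in enumerate(entries, start=1):
        row = {"rank": rank}
        for site in sorted(e.assignment):
            row[site] = e.assignment[site].smiles
        row.update(e.descriptors)
        row["predicted_pIC50"] = e.predicted_pic50
        row["extrapolation"] = e.extrapolation
        rows.append(row)
    return pd.DataFrame(rows)


def export_sdf(entries: list[LibraryEntry], template: ScaffoldTemplate, path) -> None:
    """Write assembled molecules as SDF with prediction data tags."""
    from rdkit import Chem

    hydrogen = {s: Substituent(site_label=s, smiles="[H]") for s in template.sites}
    writer = Chem.SDWriter(str(path))
    try:
        for rank, e in enumerate(entries, start=1):
            assignment = dict(hydrogen)
            assignment.update(e.assignment)
            try:
                mol = assemble(template, assignment)
            except Exception as exc:
                logger.warning("cannot assemble ranked entry %d: %s", rank, exc)
                continue
            mol.SetProp("_Name", f"entry{rank:05d}")
            mol.SetProp("predicted_pIC50", f"{e.predicted_pic50:.4f}")
            mol.SetProp("extrapolation", f"{e.extrapolation:.4f}")
            for site in sorted(e.assignment):
                mol.SetProp(f"{site}_smiles", e.assignment[site].smiles)
            writer.write(mol)
    finally:
        writer.close()
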