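"""Fatty-acid composition metrics: unsaturation index (UI), the
unsaturated/saturated ratio (U/S), and SFA/MUFA/PUFA class summaries.

UI = sum(%monoenes + 2 x %dienes + 3 x %trienes) / 100, where monoenes,
dienes and trienes carry exactly 1, 2 and 3 double bonds.  By default
species with more than 3 double bonds are weighted by their actual
double-bond count (a documented extension of the triene-capped formula);
``cap_at_trienes=True`` reproduces the strict printed formula.
U/S = total unsaturated weight % / saturated weight %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "unsaturation_index",
    "unsat_sat_ratio",
    "class_summary",
    "read_fatty_acid_table",
    "profiles_to_frame",
]


@dataclass
class FattyAcidProfile:
    """Weight-% composition of one sample.

    entries: iterable of (fatty-acid id, weight %, double-bond count).
    Weights are renormalised to 100 on construction, tolerating up to
    ``drift_tol`` of instrument drift (GC tables often sum to 99.x); a
    larger discrepancy is an error.
    """

    sample_id: str
    entries: list
    drift_tol: float = 1e-3

    def __post_init__(self):
        self.entries = [(str(fa), float(w), int(db)) for fa, w, db in self.entries]
        if any(w < 0 for _, w, _ in self.entries):
            raise ValueError("negative weight percentage")
        if any(db < 0 for _, _, db in self.entries):
            raise ValueError("negative double-bond count")
        total = sum(w for _, w, _ in self.entries)
        if total <= 0:
            raise ValueError("profile has no mass")
        if abs(total - 100.0) > self.drift_tol * 100.0:
            raise ValueError(f"weights sum to {total:.4f}, not 100")
        if abs(total - 100.0) > 1e-9:
            warnings.warn(f"renormalising weights summing to {total:.4f}", stacklevel=2)
        self.entries = [(fa, w * 100.0 / total, db) for fa, w, db in self.entries]

    def weight_by_bonds(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for _, w, db in self.entries:
            out[db] = out.get(db, 0.0) + w
        return out


def unsaturation_index(profile: FattyAcidProfile, cap_at_trienes: bool = False) -> float:
    """UI of one profile; ``cap_at_trienes`` weights >=4-bond species by 3."""
    by_db = profile.weight_by_bonds()
    ui = 0.0
    for db, w in by_db.items():
        if db == 0:
            continue
        weight = min(db, 3) if cap_at_trienes else db
        ui += weight * w
    return ui / 100.0


def unsat_sat_ratio(profile: FattyAcidProfile) -> float:
    """U/S ratio; NaN (undefined) when there is no saturated mass."""
    by_db = profile.weight_by_bonds()
    sfa = by_db.get(0, 0.0)
    ufa = sum(w for db, w in by_db.items() if db >= 1)
    if sfa <= 0:
        return float("nan")
    return ufa / sfa


def class_summary(profiles, groups: dict[str, str] | None = None) -> dict:
    """Per-sample and aggregate %SFA / %MUFA / %PUFA.

    Returns a dict with ``per_sample`` (DataFrame), ``means``/``sds``
    (overall or per group when ``groups`` maps sample -> group), and,
    for exactly two groups, ``group_ratio`` (second/first, sorted group
    names) per class.
    """
    rows = []
    for p in profiles:
        by_db = p.weight_by_bonds()
        rows.append(
            {
                "sample": p.sample_id,
                "SFA": by_db.get(0, 0.0),
                "MUFA": by_db.get(1, 0.0),
                "PUFA": sum(w for db, w in by_db.items() if db >= 2),
                "UI": unsaturation_index(p),
                "U_S": unsat_sat_ratio(p),
            }
        )
    per_sample = pd.DataFrame(rows)
    out = {"per_sample": per_sample}
    cls = ["SFA", "MUFA", "PUFA"]
    if groups:
        per_sample = per_sample.assign(group=per_sample["sample"].map(groups))
        g = per_sample.groupby("group")[cls]
        out["means"] = g.mean()
        out["sds"] = g.std(ddof=1).fillna(0.0)
        names = sorted(out["means"].index)
        if len(names) == 2:
            out["group_ratio"] = out["means"].loc[names[1]] / out["means"].loc[names[0]]
    else:
        out["means"] = per_sample[cls].mean()
        out["sds"] = per_sample[cls].std(ddof=1).fillna(0.0)
    return out


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for fa, w, db in p.entries:
            rows.append({"sample": p.sample_id, "fatty_acid": fa, "weight_percent": w, "double_bonds": db})
    return pd.DataFrame(rows)


def read_fatty_acid_table(path: str) -> list[FattyAcidProfile]:
    """Read a TSV (sample, fatty_acid, weight_percent, double_bonds)."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for sample, sub in df.groupby("sample", sort=True):
        entries = list(zip(sub["fatty_acid"], sub["weight_percent"], sub["double_bonds"]))
        profiles.append(FattyAcidProfile(sample_id=str(sample), entries=entries))
    return profiles
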