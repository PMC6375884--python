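"""Trajectory-profile enumeration, assignment and memory classification.

Expression over the ordered treatment series (baseline R0, first drought S1,
late re-watering R3, late drought S4) is summarized per gene as a short
trajectory relative to the baseline.  Candidate model trajectories are all
unit-change step vectors over the transitions (each step in {-1, 0, +1}),
excluding the flat profile; for four conditions that yields 3^3 - 1 = 26
profiles.  A gene is assigned the profile whose value vector has maximal
Pearson correlation with the gene's log-ratio trajectory.

Memory genes are stress-responsive genes whose level in a later stress (S4)
or re-watering (R3) differs significantly from the first stress (S1); memory
categories (dosage, initial, stable, accumulated, lineage) are shape
predicates on the assigned profile's value vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionTable

CATEGORIES = ("accumulated", "lineage", "initial", "stable", "dosage",
              "other-memory", "non-memory")

#: Memory-profile preset for the 4-condition design under canonical
#: numbering: the curated 16-profile list (out of 26) whose trajectories
#: differ at R3 or S4 from S1.
PAPER_MEMORY_PROFILES = (0, 1, 3, 4, 7, 9, 10, 12, 13, 15, 16, 18, 21, 22, 24, 25)


@dataclass(frozen=True)
class TrajectoryProfile:
    """A discretized trajectory: per-transition steps and cumulative values."""

    id: int
    steps: tuple[int, ...]

    @property
    def values(self) -> tuple[int, ...]:
        return (0, *np.cumsum(self.steps).tolist())


def enumerate_profiles(n_conditions: int, max_unit_change: int = 1) -> list[TrajectoryProfile]:
    """All non-flat step vectors over {-c..+c}^(T-1), canonically numbered.

    Numbering is the lexicographic rank of the step vector (steps ordered
    -c < ... < 0 < ... < +c) with the flat vector's slot removed, so ids run
    0 .. (2c+1)^(T-1) - 2.
    """
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    if max_unit_change < 1:
        raise ValueError("max_unit_change must be >= 1")
    alphabet = range(-max_unit_change, max_unit_change + 1)
    profiles = []
    next_id = 0
    for steps in itertools.product(alphabet, repeat=n_conditions - 1):
        if all(s == 0 for s in steps):
            continue
        profiles.append(TrajectoryProfile(id=next_id, steps=steps))
        next_id += 1
    return profiles


def profile_catalog(n_conditions: int = 4, max_unit_change: int = 1) -> pd.DataFrame:
    """Tabular catalog of the enumerated profiles (one row per profile)."""
    rows = []
    for p in enumerate_profiles(n_conditions, max_unit_change):
        rows.append({
            "profile_id": p.id,
            "steps": ",".join(str(s) for s in p.steps),
            "values": ",".join(str(v) for v in p.values),
            "category": categorize_values(p.values),
        })
    return pd.DataFrame(rows).set_index("profile_id")


def log_ratio_transform(trajectory, pseudocount: float = 1.0) -> np.ndarray:
    """log2 expression relative to the first time point.

    v[t] = log2((x[t] + pc) / (x[0] + pc)); v[0] is 0 by construction.
    """
    x = np.asarray(trajectory, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    shifted = x + pseudocount
    if (shifted <= 0).any():
        raise ValueError("trajectory + pseudocount must be positive")
    return np.log2(shifted / shifted[0])


def _profile_matrix(profiles) -> np.ndarray:
    """Row-wise centered, unit-norm profile value vectors."""
    vals = np.array([p.values for p in profiles], dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return centered / norms


def assign_profile(transformed_vector, profiles) -> tuple[int | None, float]:
    """Best-correlated profile for one transformed trajectory.

    Returns ``(profile_id, correlation)``; an (all-zero / constant) vector is
    unassignable and yields ``(None, nan)``.  Ties break toward the lower id.
    """
    ids, corr = assign_profiles(np.asarray(transformed_vector, float)[None, :], profiles)
    pid = ids[0]
    return (None if pid < 0 else int(pid)), float(corr[0])


def assign_profiles(matrix, profiles) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-profile assignment for many trajectories.

    matrix : (n_genes, T) array of transformed trajectories.
    Returns integer profile ids (-1 for unassignable rows) and correlations
    (nan for unassignable rows).
    """
    x = np.asarray(matrix, dtype=float)
    pm = _profile_matrix(profiles)
    if x.shape[1] != pm.shape[1]:
        raise ValueError("trajectory length does not match profile length")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    scores = np.full((x.shape[0], pm.shape[0]), -np.inf)
    scores[ok] = (centered[ok] / norms[ok, None]) @ pm.T
    # ties (within 1e-9) break toward the lower profile id
    best = scores.max(axis=1)
    tied = scores >= best[:, None] - 1e-9
    ids = np.where(ok, tied.argmax(axis=1), -1)
    id_map = np.array([p.id for p in profiles])
    out_ids = np.where(ok, id_map[ids], -1)
    corr = np.where(ok, best, np.nan)
    return out_ids, corr


def categorize_values(values) -> str:
    """Shape category of a profile value vector (0, v1, ..., v_{T-1}).

    dosage      : no change at the first stress (v1 == 0), non-flat
    initial     : responds at the first stress, then back at baseline
    lineage     : strictly monotone in one direction across all transitions
    stable      : monotone in one direction, final transition flat
    accumulated : monotone in one direction with an interior hold then a
                  further step (rise, hold, rise again)
    anything else is 'other-memory'.
    """
    v = tuple(int(x) for x in values)
    if all(x == 0 for x in v):
        raise ValueError("flat profile has no category")
    steps = tuple(v[i + 1] - v[i] for i in range(len(v) - 1))
    if v[1] == 0:
        return "dosage"
    if all(x == 0 for x in v[2:]):
        return "initial"
    s = 1 if steps[0] > 0 else -1
    if all(st in (0, s) for st in steps):
        if all(st == s for st in steps):
            return "lineage"
        if steps[-1] == 0:
            return "stable"
        return "accumulated"
    return "other-memory"


def categorize_memory(profile_id: int | None, is_memory: bool,
                      profiles=None) -> str:
    """Memory category for one gene given its assigned profile and flag."""
    if not is_memory:
        return "non-memory"
    if profile_id is None or profile_id < 0:
        return "other-memory"
    if profiles is None:
        profiles = enumerate_profiles(4)
    by_id = {p.id: p for p in profiles}
    return categorize_values(by_id[profile_id].values)


def flag_memory(de_results: dict[str, pd.DataFrame], rule: str = "any",
                baseline: str = "R0", first_stress: str = "S1",
                later: tuple[str, ...] = ("R3", "S4")) -> pd.DataFrame:
    """Per-gene memory call from differential-expression screens.

    A gene is a memory gene iff it is responsive to the stress series
    (DE in at least one <condition>_vs_<baseline> contrast) AND its level in
    a later condition differs from the first stress (any / all of the
    <later>_vs_<first_stress> contrasts, per ``rule``).
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    resp_keys = [f"{c}_vs_{baseline}" for c in (first_stress, *later)]
    mem_keys = [f"{c}_vs_{first_stress}" for c in later]
    for key in resp_keys + mem_keys:
        if key not in de_results:
            raise KeyError(f"missing contrast {key}")
    genes = de_results[resp_keys[0]].index
    changed = {k: (de_results[k]["status"] != "unchanged").reindex(genes, fill_value=False)
               for k in resp_keys + mem_keys}
    responsive = np.logical_or.reduce([changed[k].to_numpy() for k in resp_keys])
    mem_cols = np.column_stack([changed[k].to_numpy() for k in mem_keys])
    differs = mem_cols.any(axis=1) if rule == "any" else mem_cols.all(axis=1)
    out = pd.DataFrame({"responsive": responsive,
                        "is_memory": responsive & differs}, index=genes)
    for k in mem_keys:
        out[f"de_{k}"] = changed[k].to_numpy()
    return out


def flag_memory_by_profiles(profile_ids, memory_profiles=PAPER_MEMORY_PROFILES) -> np.ndarray:
    """Preset memory call: membership of the assigned profile in a fixed list
    (default: the curated 16-profile list for the 4-condition design)."""
    ids = np.asarray(profile_ids)
    return np.isin(ids, np.asarray(memory_profiles))


def classify_genes(table: ExpressionTable, de_results: dict[str, pd.DataFrame],
                   rule: str = "any", pseudocount: float = 1.0,
                   max_unit_change: int = 1,
                   memory_preset: bool = False) -> pd.DataFrame:
    """Full per-gene classification: profile, correlation, memory, category.

    Condition trajectories are replicate-averaged FPKM values in the table's
    condition order; with ``memory_preset`` the memory flag comes from the
    curated profile list instead of the DE-based rule.
    """
    conditions = table.conditions
    profiles = enumerate_profiles(len(conditions), max_unit_change)
    means = table.condition_means(table.fpkm(robust=True))[conditions]
    x = means.to_numpy(dtype=float)
    shifted = x + pseudocount
    transformed = np.log2(shifted / shifted[:, [0]])
    ids, corr = assign_profiles(transformed, profiles)
    out = pd.DataFrame({"profile_id": ids, "correlation": corr}, index=means.index)
    if memory_preset:
        out["responsive"] = ids >= 0
        out["is_memory"] = flag_memory_by_profiles(ids)
    else:
        flags = flag_memory(de_results, rule=rule,
                            baseline=conditions[0], first_stress=conditions[1],
                            later=tuple(conditions[2:]))
        flags = flags.reindex(means.index)
        out["responsive"] = flags["responsive"]
        out["is_memory"] = flags["is_memory"]
        for c in flags.columns:
            if c.startswith("de_"):
                out[c] = flags[c]
    out["category"] = [
        categorize_memory(None if pid < 0 else int(pid), bool(mem), profiles)
        for pid, mem in zip(out["profile_id"], out["is_memory"])
    ]
    return out
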