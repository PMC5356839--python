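"""Per-gene two-group Mann-Whitney tests and age correlation.

The standardized statistic uses the tie-corrected variance and a 0.5
continuity correction (both individually toggleable); two-sided p-values
come from the normal approximation.  An exact-enumeration mode is provided
for small groups as an independent oracle.

Sign convention: the first group is MH and the second MPM, so genes higher
in MPM get a negative z.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from .core import CodesetError, CountMatrix, Stage

ALPHA_STRICT = 0.005
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class DEResult:
    gene: str
    z: float
    p: float
    direction: str  # up_in_MPM | down_in_MPM


@dataclass(frozen=True)
class AgeCorrelation:
    gene: str
    group: str  # all | MPM | MH
    rho_spearman: float
    p: float
    constant: bool = False


def z_to_p(z: float) -> float:
    """Two-sided normal p-value for a standardized statistic."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * norm.sf(abs(z)))


def mann_whitney_z(x_group_a, x_group_b, *, continuity: bool = True,
                   tie_correction: bool = True) -> tuple[float, float]:
    """Standardized Mann-Whitney comparison of two samples.

    Returns ``(z, p)`` where z is negative when the second group tends to
    have larger values.  Degenerate input (all values tied across both
    groups) yields ``(0, 1)``.
    """
    a = np.asarray(x_group_a, dtype=float)
    b = np.asarray(x_group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    var = n1 * n2 * (n + 1) / 12.0
    if tie_correction:
        _, t = np.unique(np.concatenate([a, b]), return_counts=True)
        var -= n1 * n2 * np.sum(t**3 - t) / (12.0 * n * (n - 1)) if n > 1 else 0.0
    if var <= 0:
        return 0.0, 1.0

    diff = u1 - mu
    if continuity:
        adj = max(abs(diff) - 0.5, 0.0)
    else:
        adj = abs(diff)
    z = np.sign(diff) * adj / np.sqrt(var)
    return float(z), z_to_p(float(z))


def mann_whitney_exact_p(x_group_a, x_group_b) -> float:
    """Exact two-sided p by enumeration of all group assignments.

    Feasible for small samples only (n1 + n2 <= ~14); the null distribution
    of U is built over every choice of n1 positions among the pooled
    midranks, which also handles ties exactly.
    """
    a = np.asarray(x_group_a, dtype=float)
    b = np.asarray(x_group_b, dtype=float)
    n1, n2 = a.size, b.size
    n = n1 + n2
    if comb(n, n1) > 500_000:
        raise ValueError("exact enumeration infeasible for this size")
    ranks = rankdata(np.concatenate([a, b]))
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def run_diffexp(m: CountMatrix, *, continuity: bool = True,
                tie_correction: bool = True) -> list[DEResult]:
    """One Mann-Whitney result per Endogenous gene, MH vs MPM.

    Results are ordered by direction (up first) then ascending p.
    """
    if m.stage != Stage.BIO_NORMALIZED:
        raise CodesetError(f"diffexp expects normalized counts, got {m.stage.value}")
    labels = np.array(m.labels)
    mh = labels == "MH"
    mpm = labels == "MPM"
    if mh.sum() < 2 or mpm.sum() < 2:
        raise ValueError(
            f"need >=2 samples per class, got MH={int(mh.sum())} MPM={int(mpm.sum())}"
        )
    expr = m.endogenous_frame()
    results = []
    for gene, row in expr.iterrows():
        v = row.to_numpy(float)
        z, p = mann_whitney_z(v[mh], v[mpm], continuity=continuity,
                              tie_correction=tie_correction)
        direction = "up_in_MPM" if z < 0 else "down_in_MPM"
        results.append(DEResult(gene=str(gene), z=z, p=p, direction=direction))
    results.sort(key=lambda r: (r.direction != "up_in_MPM", r.p, r.gene))
    return results


def count_significant(results, alpha: float) -> tuple[int, int]:
    """(n_up_in_MPM, n_down_in_MPM) with p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_up = sum(1 for r in results if r.p < alpha and r.direction == "up_in_MPM")
    n_down = sum(1 for r in results if r.p < alpha and r.direction == "down_in_MPM")
    return n_up, n_down


def age_correlation(m: CountMatrix) -> list[AgeCorrelation]:
    """Spearman correlation of each gene with age, overall and per label."""
    ages = np.array([np.nan if s.age is None else s.age for s in m.samples])
    if np.isnan(ages).any():
        missing = [s.sample_id for s, a in zip(m.samples, ages) if np.isnan(a)]
        raise ValueError(f"age missing for samples: {missing}")
    labels = np.array(m.labels)
    expr = m.endogenous_frame()
    groups = {"all": np.ones(len(ages), dtype=bool)}
    for lab in ("MPM", "MH"):
        mask = labels == lab
        if mask.sum() >= 3:
            groups[lab] = mask
    out = []
    for gene, row in expr.iterrows():
        v = row.to_numpy(float)
        for gname, mask in groups.items():
            if np.ptp(v[mask]) == 0 or np.ptp(ages[mask]) == 0:
                out.append(AgeCorrelation(str(gene), gname, 0.0, 1.0, True))
                continue
            rho, p = spearmanr(v[mask], ages[mask])
            out.append(AgeCorrelation(str(gene), gname, float(rho), float(p)))
    return out


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene": r.gene, "z": r.z, "p": r.p, "direction": r.direction}
        for r in results
    ])
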