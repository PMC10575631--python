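"""Reproducibility-optimized differential abundance (ROTS).

The statistic family is d = |m_b - m_a| / (alpha1 + alpha2 * s), where s is
the pooled standard error of the mean difference. (alpha1=0, alpha2=1) is
the ordinary absolute t-statistic, (alpha1=1, alpha2=0) the absolute mean
difference. The free parameters and the top-list size k are chosen to
maximize the reproducibility Z-score

    Z_k(alpha) = (R_k(alpha) - R0_k(alpha)) / sd_k(alpha)

where R_k is the mean top-k overlap of rankings across pairs of bootstrap
resamples (samples resampled within groups), R0_k the same on
group-label-permuted data, and sd_k the bootstrap SD of the observed
overlaps. Significance is assessed by group-label permutations with a
pooled null: p(g) = (1 + #{null d >= d(g)}) / (1 + total null count), and a
permutation FDR = (mean per-permutation null exceedances) / (observed
exceedances), clipped and made monotone along the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import StudyDesign, ValidationError

DEFAULT_GRID_ALPHA1 = (0.0, 0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0)
DEFAULT_GRID_K = (25, 50, 100, 200, 400)


@dataclass
class RotsParams:
    """Grid and resampling sizes for the ROTS optimization.

    ``alpha1``/``alpha2`` fix the statistic and skip optimization when both
    are given. B is the number of bootstrap pairs, P the number of label
    permutations for p-values.
    """

    alpha1: float | None = None
    alpha2: float | None = None
    grid_alpha1: tuple[float, ...] = DEFAULT_GRID_ALPHA1
    grid_k: tuple[int, ...] = DEFAULT_GRID_K
    B: int = 500
    P: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_alpha1 or not self.grid_k:
            raise ValidationError("grids must be non-empty")
        if self.B < 2:
            raise ValidationError("B must be >= 2")
        if self.P < 1:
            raise ValidationError("P must be >= 1")

    def candidates(self) -> list[tuple[float, float]]:
        """Statistic family grid: (a1, 1) for each a1, plus the (1, 0) limit."""
        cand = [(float(a1), 1.0) for a1 in sorted(self.grid_alpha1)]
        cand.append((1.0, 0.0))
        return cand


@dataclass
class RotsOptimum:
    alpha1: float
    alpha2: float
    k: int
    z: float
    grid: pd.DataFrame  # one row per (alpha1, alpha2, k): R, R0, sd, Z
    overlaps: np.ndarray  # B x K observed overlaps at the chosen statistic
    null_overlaps: np.ndarray  # B x K null overlaps at the chosen statistic
    k_grid: tuple[int, ...]


def _stat_core(
    x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, alpha1: float, alpha2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (d, mean difference) over all protein rows."""
    a = x[:, idx_a]
    b = x[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    diff = mb - ma
    if alpha2 != 0.0:
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        denom = alpha1 + alpha2 * se
    else:
        denom = np.full(diff.shape, alpha1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(diff) / denom
    d = np.where(denom > 0, d, np.where(np.abs(diff) > 0, np.inf, 0.0))
    return d, diff


def rots_statistic(
    group_a: np.ndarray, group_b: np.ndarray, alpha1: float, alpha2: float
) -> float:
    """The ROTS statistic for one protein (scalar form)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("each group needs >=2 finite values")
    if alpha1 == 0.0 and alpha2 == 0.0:
        raise ValidationError("alpha1 and alpha2 cannot both be zero")
    x = np.concatenate([a, b])[None, :]
    d, _ = _stat_core(x, np.arange(a.size), a.size + np.arange(b.size), alpha1, alpha2)
    return float(d[0])


def topk_overlap(ranking_a, ranking_b, k: int) -> float:
    """|top-k(a) ∩ top-k(b)| / k for two rankings of the same id universe."""
    ra = list(ranking_a)
    rb = list(ranking_b)
    if set(ra) != set(rb):
        raise ValidationError("rankings must cover the same ids")
    if not 1 <= k <= len(ra):
        raise ValidationError(f"k={k} out of range [1, {len(ra)}]")
    return len(set(ra[:k]) & set(rb[:k])) / k


def _group_indices(
    matrix: pd.DataFrame, design: StudyDesign, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    ref, test = contrast
    cols = list(matrix.columns)
    idx_a = np.array([cols.index(s) for s in design.samples_for(ref) if s in cols])
    idx_b = np.array([cols.index(s) for s in design.samples_for(test) if s in cols])
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValidationError(f"contrast {contrast} needs >=2 samples per group")
    return idx_a, idx_b


def _overlap_profile(d1: np.ndarray, d2: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Top-k overlap between two statistic vectors for every k at once."""
    n = d1.size
    r1 = np.empty(n, dtype=np.int64)
    r2 = np.empty(n, dtype=np.int64)
    r1[np.argsort(-d1, kind="stable")] = np.arange(n)
    r2[np.argsort(-d2, kind="stable")] = np.arange(n)
    return np.array([np.count_nonzero((r1 < k) & (r2 < k)) / k for k in ks])


def rots_optimize(
    matrix: pd.DataFrame,
    design: StudyDesign,
    params: RotsParams,
    contrast: tuple[str, str] | None = None,
) -> RotsOptimum:
    """Choose (alpha1, alpha2, k) maximizing bootstrap top-list reproducibility.

    Ties are broken toward smaller alpha1 then smaller k; the pure
    mean-difference statistic (1, 0) is considered last.
    """
    contrast = contrast or design.contrasts[0]
    idx_a, idx_b = _group_indices(matrix, design, contrast)
    x = matrix.values.astype(float)
    n = x.shape[0]
    ks = np.array([k for k in params.grid_k if k <= n], dtype=int)
    if ks.size == 0:
        raise ValidationError("no k in grid_k is <= number of proteins")
    rng = np.random.default_rng(params.seed)
    B = params.B
    all_idx = np.concatenate([idx_a, idx_b])
    na, nb = idx_a.size, idx_b.size

    # pre-draw resampling plans so every candidate statistic sees the same ones
    boot_a = [(rng.choice(idx_a, na), rng.choice(idx_a, na)) for _ in range(B)]
    boot_b = [(rng.choice(idx_b, nb), rng.choice(idx_b, nb)) for _ in range(B)]
    null_plans = []
    for _ in range(B):
        perm = rng.permutation(all_idx)
        pa, pb = perm[:na], perm[na:]
        null_plans.append(
            (rng.choice(pa, na), rng.choice(pb, nb), rng.choice(pa, na), rng.choice(pb, nb))
        )

    rows = []
    best = None
    for a1, a2 in params.candidates():
        if params.alpha1 is not None and params.alpha2 is not None:
            if (a1, a2) != (params.alpha1, params.alpha2):
                continue
        obs = np.empty((B, ks.size))
        nul = np.empty((B, ks.size))
        for b in range(B):
            (a1s, a2s), (b1s, b2s) = boot_a[b], boot_b[b]
            d1, _ = _stat_core(x, a1s, b1s, a1, a2)
            d2, _ = _stat_core(x, a2s, b2s, a1, a2)
            obs[b] = _overlap_profile(d1, d2, ks)
            pa1, pb1, pa2, pb2 = null_plans[b]
            e1, _ = _stat_core(x, pa1, pb1, a1, a2)
            e2, _ = _stat_core(x, pa2, pb2, a1, a2)
            nul[b] = _overlap_profile(e1, e2, ks)
        r = obs.mean(axis=0)
        r0 = nul.mean(axis=0)
        sd = obs.std(axis=0, ddof=1)
        z = (r - r0) / np.maximum(sd, 1e-12)
        for j, k in enumerate(ks):
            rows.append((a1, a2, int(k), r[j], r0[j], sd[j], z[j]))
        j_best = int(np.argmax(z))
        if best is None or z[j_best] > best.z:
            best = RotsOptimum(
                alpha1=a1, alpha2=a2, k=int(ks[j_best]), z=float(z[j_best]),
                grid=None, overlaps=obs, null_overlaps=nul, k_grid=tuple(int(k) for k in ks),
            )
    best.grid = pd.DataFrame(
        rows, columns=["alpha1", "alpha2", "k", "R", "R0", "sd", "Z"]
    )
    return best


def permutation_pvalues(
    matrix: pd.DataFrame,
    design: StudyDesign,
    alpha1: float,
    alpha2: float,
    P: int,
    seed: int = 0,
    contrast: tuple[str, str] | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Pooled-null permutation p-values and permutation FDR per protein.

    With ``exhaustive=True`` every distinct group-label assignment is
    enumerated instead of sampling P random permutations (only sensible
    for small designs).
    """
    if P < 1:
        raise ValidationError("P must be >= 1")
    contrast = contrast or design.contrasts[0]
    idx_a, idx_b = _group_indices(matrix, design, contrast)
    x = matrix.values.astype(float)
    n = x.shape[0]
    d_obs, diff = _stat_core(x, idx_a, idx_b, alpha1, alpha2)
    all_idx = np.concatenate([idx_a, idx_b])
    na = idx_a.size
    if exhaustive:
        from itertools import combinations

        splits = list(combinations(range(all_idx.size), na))
        null = np.empty((len(splits), n))
        for p_i, pick in enumerate(splits):
            mask = np.zeros(all_idx.size, dtype=bool)
            mask[list(pick)] = True
            null[p_i], _ = _stat_core(x, all_idx[mask], all_idx[~mask], alpha1, alpha2)
        P = len(splits)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((P, n))
        for p_i in range(P):
            perm = rng.permutation(all_idx)
            null[p_i], _ = _stat_core(x, perm[:na], perm[na:], alpha1, alpha2)
    flat = np.sort(null, axis=None)
    total = flat.size
    # exceedance counts in the pooled null, via right-edge search
    ge_null = total - np.searchsorted(flat, d_obs, side="left")
    pvals = (1.0 + ge_null) / (1.0 + total)
    obs_sorted = np.sort(d_obs)
    ge_obs = n - np.searchsorted(obs_sorted, d_obs, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = (ge_null / P) / ge_obs
    fdr_raw = np.clip(fdr_raw, 0.0, 1.0)
    # enforce monotonicity: FDR never decreases as the statistic decreases
    order = np.argsort(-d_obs, kind="stable")
    fdr_sorted = np.minimum.accumulate(fdr_raw[order][::-1])[::-1]
    fdr = np.empty(n)
    fdr[order] = fdr_sorted
    return pd.DataFrame(
        {"d": d_obs, "mean_diff": diff, "p": pvals, "fdr": fdr}, index=matrix.index
    )


def select_de(
    result: pd.DataFrame, p_cut: float = 0.05, fdr_cut: float = 0.25
) -> tuple[set, set]:
    """Differential proteins at p < p_cut and FDR <= fdr_cut, split up/down.

    The p threshold is strict and the FDR threshold inclusive. Direction is
    the sign of the test-minus-reference mean difference.
    """
    if len(result) == 0:
        return set(), set()
    sel = (result["p"] < p_cut) & (result["fdr"] <= fdr_cut)
    up = set(result.index[sel & (result["mean_diff"] > 0)])
    down = set(result.index[sel & (result["mean_diff"] < 0)])
    return up, down


def venn_partition(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Counts of the 7 disjoint regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }


@dataclass
class DifferentialRun:
    """Full per-contrast differential result plus the chosen statistic."""

    table: pd.DataFrame
    optimum: RotsOptimum


def run_differential(
    normalized: pd.DataFrame,
    design: StudyDesign,
    params: RotsParams,
    contrast: tuple[str, str] | None = None,
    counts: pd.DataFrame | None = None,
    p_cut: float = 0.05,
    fdr_cut: float = 0.25,
) -> DifferentialRun:
    """Optimize the statistic, compute permutation p/FDR and select DE proteins.

    If the raw count matrix is supplied, signed fold changes (pseudocount 1,
    count scale) and total spectral counts are attached for downstream
    filtering.
    """
    contrast = contrast or design.contrasts[0]
    opt = rots_optimize(normalized, design, params, contrast)
    table = permutation_pvalues(
        normalized, design, opt.alpha1, opt.alpha2, params.P,
        seed=params.seed + 1, contrast=contrast,
    )
    table["selected"] = (table["p"] < p_cut) & (table["fdr"] <= fdr_cut)
    table["direction"] = np.where(table["mean_diff"] >= 0, "up", "down")
    if counts is not None:
        from .prioritize import fold_changes

        common = table.index.intersection(counts.index)
        table.loc[common, "fold_change"] = fold_changes(
            counts.loc[common], design, contrast
        )
        table.loc[common, "total_spectra"] = counts.loc[common].sum(axis=1)
    return DifferentialRun(table=table, optimum=opt)
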