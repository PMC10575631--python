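"""Synthetic spectral-count data with known planted truth.

Emulates a label-free shotgun proteomics experiment: a few thousand
proteins quantified by MS/MS spectral counts across two (or more) small
groups of biological samples, with sparse, overdispersed counts. Counts
are negative-binomial with protein-specific baseline means drawn
log-normally (Var = mu + dispersion * mu^2), a planted subset of proteins
shifted between groups by ``effect_log2`` on the log2 scale, and detection
dropout applied by independent thinning of whole cells. Gene-set
collections are drawn over the simulated protein universe with a planted
subset of sets whose membership is biased toward the differential
proteins, so enrichment and prioritization stages can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SimTruth, StudyDesign, ValidationError
from .genesets import GeneSetCollection


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults mirror the scale of a 16-sample organoid spectral-count study:
    ~4,000 proteins in two groups of 8, moderate overdispersion
    (Var = mu + 0.5 mu^2), an extra 5% of cells lost to run-level detection
    dropout (on top of the abundance-dependent zeros the count model itself
    produces), planted ~2.8-fold shifts on 10% of proteins, and a 500-set
    collection with 10% of sets carrying planted signal.
    """

    n_proteins: int = 4000
    n_samples_per_group: int = 8
    n_groups: int = 2
    de_fraction: float = 0.1
    effect_log2: float = 1.5
    dispersion: float = 0.5
    detection_prob: float = 0.95
    n_sets: int = 500
    set_size_range: tuple[int, int] = (10, 50)
    planted_set_fraction: float = 0.1
    seed: int = 0
    # baseline log-normal abundance distribution (natural-log scale)
    baseline_log_mean: float = field(default=2.3, repr=False)
    baseline_log_sd: float = field(default=1.2, repr=False)

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be a positive integer")
        if self.n_samples_per_group < 1:
            raise ValidationError("n_samples_per_group must be a positive integer")
        if self.n_groups < 2:
            raise ValidationError("n_groups must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.effect_log2 <= 0:
            raise ValidationError("effect_log2 must be > 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValidationError("detection_prob must lie in (0, 1]")
        if self.n_sets < 1:
            raise ValidationError("n_sets must be a positive integer")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("set_size_range must be an increasing pair of ints >= 1")
        if not 0.0 <= self.planted_set_fraction <= 1.0:
            raise ValidationError("planted_set_fraction must lie in [0, 1]")

    @property
    def n_planted(self) -> int:
        return int(round(self.de_fraction * self.n_proteins))


def _group_labels(n_groups: int) -> list[str]:
    if n_groups == 2:
        return ["healthy", "patient"]
    return ["healthy"] + [f"patient{i}" for i in range(1, n_groups)]


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, StudyDesign, SimTruth]:
    """Draw a protein x sample spectral-count matrix with planted effects.

    Returns the count matrix, the study design (reference condition vs each
    patient condition) and the planted truth. Planted proteins shift every
    non-reference group's mean by ``2**(+-effect_log2)``, direction drawn
    uniformly per protein.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    labels = _group_labels(cfg.n_groups)
    samples, conditions = [], []
    for lab in labels:
        for r in range(1, cfg.n_samples_per_group + 1):
            samples.append(f"{lab}_{r}")
            conditions.append(lab)

    base_mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_proteins)

    n_de = cfg.n_planted
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5
    effect = np.zeros(cfg.n_proteins)
    effect[de_idx] = np.where(up, cfg.effect_log2, -cfg.effect_log2)

    n_samples = len(samples)
    mu = np.tile(base_mu[:, None], (1, n_samples))
    is_test = np.array([c != labels[0] for c in conditions])
    mu[:, is_test] *= 2.0 ** effect[:, None]

    # NB with Var = mu + dispersion*mu^2  <=>  shape r = 1/dispersion
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    if cfg.detection_prob < 1.0:
        detected = rng.random(counts.shape) < cfg.detection_prob
        counts = counts * detected

    matrix = pd.DataFrame(counts, index=proteins, columns=samples)
    design = StudyDesign(
        conditions=pd.Series(conditions, index=samples),
        contrasts=[(labels[0], lab) for lab in labels[1:]],
    )
    truth = SimTruth(
        de_proteins={proteins[i] for i in de_idx},
        directions={
            proteins[i]: ("up" if u else "down") for i, u in zip(de_idx, up)
        },
    )
    return matrix, design, truth


def simulate_peptides(
    matrix: pd.DataFrame,
    peptides_per_protein_range: tuple[int, int] = (1, 5),
    seed: int = 0,
) -> pd.DataFrame:
    """Partition each protein's per-sample counts across synthetic peptides.

    Each protein gets a random number of peptides in the given range, with
    Dirichlet-weighted multinomial splitting of every sample's count, so
    summing peptide rows per protein recovers the input matrix exactly.
    Only nonzero cells are emitted (long format; absent rows mean zero).
    """
    lo, hi = peptides_per_protein_range
    if lo < 1 or hi < lo:
        raise ValidationError("peptides_per_protein_range lower bound must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str, int]] = []
    samples = list(matrix.columns)
    for prot, row in zip(matrix.index, matrix.values):
        n_pep = int(rng.integers(lo, hi + 1))
        weights = rng.dirichlet(np.ones(n_pep))
        # one multinomial draw per sample, vectorized over samples
        split = rng.multinomial(row.astype(np.int64), weights)
        for j, samp in enumerate(samples):
            for k in range(n_pep):
                c = int(split[j, k])
                if c > 0:
                    records.append((prot, f"{prot}_pep{k + 1}", samp, c))
    return pd.DataFrame(
        records, columns=["protein_id", "peptide_id", "sample_id", "spectral_count"]
    )


def simulate_genesets(
    protein_ids: list[str],
    cfg: SimConfig,
    truth: SimTruth,
    de_member_frac: float = 0.8,
) -> GeneSetCollection:
    """Draw a gene-set collection over the simulated proteins.

    ``round(planted_set_fraction * n_sets)`` sets are planted: a
    ``de_member_frac`` share of their members is drawn from the planted
    differential proteins, the rest uniformly from the others. Remaining
    sets are uniform draws from the whole universe. Planted set names are
    recorded in ``truth.planted_sets`` (in place).
    """
    if not protein_ids:
        raise ValidationError("protein_ids must be non-empty")
    lo, hi = cfg.set_size_range
    if hi > len(protein_ids):
        raise ValidationError(
            f"set_size_range upper bound {hi} exceeds number of proteins {len(protein_ids)}"
        )
    if not 0.0 <= de_member_frac <= 1.0:
        raise ValidationError("de_member_frac must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)
    ids = np.asarray(protein_ids)
    de = np.asarray(sorted(truth.de_proteins & set(protein_ids)))
    other = np.asarray(sorted(set(protein_ids) - set(de)))
    n_planted = int(round(cfg.planted_set_fraction * cfg.n_sets))
    if len(de) == 0:
        n_planted = 0

    coll = GeneSetCollection(label="simulated")
    width = max(4, len(str(cfg.n_sets)))
    for s in range(cfg.n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{s:0{width}d}"
        if s < n_planted:
            k_de = min(int(round(de_member_frac * size)), len(de))
            members = list(rng.choice(de, size=k_de, replace=False))
            k_rest = size - k_de
            if k_rest > 0:
                pool = other if len(other) >= k_rest else ids
                members += list(rng.choice(pool, size=k_rest, replace=False))
            members = list(dict.fromkeys(members))[:size]
            coll.add(name, members, "planted")
            truth.planted_sets.add(name)
        else:
            members = list(rng.choice(ids, size=size, replace=False))
            coll.add(name, members, "background")
    return coll


def simulate_normal_groups(
    n_proteins: int,
    n_per_group: int,
    de_fraction: float = 0.0,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, StudyDesign, SimTruth]:
    """Gaussian normalized-scale matrix with planted mean shifts.

    A controlled benchmark input for the differential-abundance stage: unit
    within-group SD, so ``effect_sd`` is the planted effect in pooled-SD
    units exactly. Complements :func:`simulate_counts`, which exercises the
    count -> normalization path.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    samples = [f"healthy_{i+1}" for i in range(n_per_group)] + [
        f"patient_{i+1}" for i in range(n_per_group)
    ]
    values = rng.standard_normal((n_proteins, 2 * n_per_group))
    n_de = int(round(de_fraction * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5
    shift = np.where(up, effect_sd, -effect_sd)
    values[de_idx, n_per_group:] += shift[:, None]
    design = StudyDesign(
        conditions=pd.Series(
            ["healthy"] * n_per_group + ["patient"] * n_per_group, index=samples
        ),
        contrasts=[("healthy", "patient")],
    )
    truth = SimTruth(
        de_proteins={proteins[i] for i in de_idx},
        directions={proteins[i]: ("up" if u else "down") for i, u in zip(de_idx, up)},
    )
    return pd.DataFrame(values, index=proteins, columns=samples), design, truth
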