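"""Protein prioritization: pathway frequency, percentile cut, filter cascade,
and disease-library over-representation.

The frequency of a protein is the number of significant pathways whose
enriched (leading-edge) component contains it, pooled across collections
and contrasts. Candidates are the proteins at or above the nearest-rank
percentile of that frequency distribution which additionally pass a signed
fold-change threshold (|fc| >= 3 by default, pseudocount-1 count-scale
ratio, reported as r for r >= 1 and -1/r otherwise) and a total
spectral-count threshold (>= 10 by default). Disease relevance is scored
by one-sided Fisher/hypergeometric over-representation of the candidate
set in each disease-library term, followed by a per-protein count of the
significant terms containing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import StudyDesign, ValidationError
from .genesets import GeneSetCollection


def frequency_table(enrichments: list[pd.DataFrame]) -> pd.Series:
    """Occurrences of each protein across enriched components of significant sets.

    Accepts the per-collection tables produced by
    :func:`protprio.gsea.enrich_collection` (columns ``significant`` and
    ``component``); non-significant pathways contribute nothing.
    """
    counts: dict[str, int] = {}
    for df in enrichments:
        if len(df) == 0:
            continue
        for comp in df.loc[df["significant"], "component"]:
            if not comp:
                continue
            for prot in comp.split("|"):
                counts[prot] = counts.get(prot, 0) + 1
    freq = pd.Series(counts, dtype=int).sort_index()
    freq.name = "frequency"
    return freq


def percentile_select(freq: pd.Series, percentile: float = 90.0) -> set:
    """Proteins at or above the nearest-rank percentile of the frequencies.

    The threshold is the nearest-rank percentile value (ceil(q/100 * n)-th
    smallest frequency); all ties at the threshold are included.
    """
    if not 0.0 < percentile < 100.0:
        raise ValidationError("percentile must lie in (0, 100)")
    if len(freq) == 0:
        raise ValidationError("frequency table is empty")
    vals = np.sort(freq.to_numpy())
    rank = int(np.ceil(percentile / 100.0 * len(vals)))  # 1-based nearest rank
    threshold = vals[rank - 1]
    return set(freq.index[freq >= threshold])


def fold_changes(
    counts: pd.DataFrame, design: StudyDesign, contrast: tuple[str, str]
) -> pd.Series:
    """Signed count-scale fold change test vs reference, pseudocount 1.

    r = (mean_test + 1) / (mean_ref + 1); reported as r when r >= 1 and
    -1/r otherwise, so up/down thresholds at +-c are symmetric.
    """
    ref, test = contrast
    ref_cols = [s for s in design.samples_for(ref) if s in counts.columns]
    test_cols = [s for s in design.samples_for(test) if s in counts.columns]
    if not ref_cols or not test_cols:
        raise ValidationError(f"contrast {contrast} has no samples in the matrix")
    m_ref = counts[ref_cols].mean(axis=1) + 1.0
    m_test = counts[test_cols].mean(axis=1) + 1.0
    r = m_test / m_ref
    signed = np.where(r >= 1.0, r, -1.0 / r)
    return pd.Series(signed, index=counts.index, name="fold_change")


def filter_cascade(
    freq: pd.Series,
    fold_change: pd.Series,
    total_spectra: pd.Series,
    percentile: float = 90.0,
    fc_cut: float = 3.0,
    spectra_cut: int = 10,
) -> pd.DataFrame:
    """Apply the percentile, fold-change and spectral-count filters.

    All three flags are computed independently (so the filters commute);
    final candidates are the conjunction. Returns one row per protein in
    the frequency table with per-filter boolean columns and the direction
    implied by the fold-change sign.
    """
    idx = freq.index
    selected = percentile_select(freq, percentile)
    fc = fold_change.reindex(idx)
    spectra = total_spectra.reindex(idx)
    out = pd.DataFrame(
        {
            "frequency": freq,
            "fold_change": fc,
            "total_spectra": spectra,
            "direction": np.where(fc >= 0, "up", "down"),
            "passed_percentile": idx.isin(list(selected)),
            "passed_fc": fc.abs() >= fc_cut,
            "passed_spectra": spectra >= spectra_cut,
        },
        index=idx,
    )
    out["candidate"] = (
        out["passed_percentile"] & out["passed_fc"] & out["passed_spectra"]
    )
    out.index.name = "protein_id"
    return out.sort_index()


def term_overrepresentation(
    query: set,
    library: GeneSetCollection,
    universe: set,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric tail) p per library term.

    Terms are restricted to the quantified-protein universe before testing,
    reflecting detection bias: only proteins that could have been observed
    count toward either margin.
    """
    if not query:
        raise ValidationError("query set is empty")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for name in library.names():
        members = set(library.members(name)) & universe
        k = len(members & query)
        # P[X >= k], X ~ Hypergeom(N=n_univ, K=|term|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append(
            {
                "library": library.label,
                "term": name,
                "term_size": len(members),
                "overlap": k,
                "p": min(p, 1.0),
                "significant": p < p_cut,
            }
        )
    return pd.DataFrame(
        rows, columns=["library", "term", "term_size", "overlap", "p", "significant"]
    )


def disease_frequency(
    candidates: set,
    libraries: list[GeneSetCollection],
    overrep: list[pd.DataFrame],
) -> pd.DataFrame:
    """Count, per candidate, the significant disease terms containing it.

    ``overrep`` holds the per-library over-representation tables (same
    order as ``libraries``). Proteins with count >= 1 form the clinically
    related subset.
    """
    counts = {p: 0 for p in candidates}
    terms: dict[str, list[str]] = {p: [] for p in candidates}
    for lib, table in zip(libraries, overrep):
        sig = set(table.loc[table["significant"], "term"])
        for name in sig:
            members = set(lib.members(name))
            for prot in candidates & members:
                counts[prot] += 1
                terms[prot].append(f"{lib.label}:{name}")
    out = pd.DataFrame(
        {
            "protein_id": sorted(candidates),
            "n_disease_terms": [counts[p] for p in sorted(candidates)],
            "disease_terms": ["|".join(sorted(terms[p])) for p in sorted(candidates)],
        }
    )
    out["clinically_related"] = out["n_disease_terms"] >= 1
    return out
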