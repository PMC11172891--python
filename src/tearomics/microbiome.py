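"""Downstream statistics on taxonomic relative-abundance tables.

Works on profiler-style tables whose rows are rank-prefixed lineage strings
(``k__Bacteria|p__Firmicutes|...|s__Staphylococcus_aureus``): rank
aggregation, lumping of rare taxa into an "Under 1%" bin, Shannon-diversity
group comparison, presence/absence association by Fisher's exact test, and
community-level ordination (PCA) with PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import SampleAnnotation, TaxonAbundanceTable
from .stats import (
    ContingencyTable2x2,
    PermanovaResult,
    fisher_exact_2x2,
    pca,
    permanova,
    shannon_index,
    two_sample_summary,
    welch_t_test,
)

__all__ = [
    "RANK_PREFIXES",
    "GroupComparisonResult",
    "parse_rank",
    "aggregate_level",
    "lump_rare",
    "diversity_compare",
    "presence_absence_test",
    "community_comparison",
    "UNDER_LABEL",
]

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

UNDER_LABEL = "Under 1%"


@dataclass
class GroupComparisonResult:
    """Outcome of one group-level statistical comparison."""

    statistic_name: str
    statistic: float
    p_value: float
    group_summaries: dict
    metadata: dict


def parse_rank(lineage: str, rank: str) -> str | None:
    """Extract the name at ``rank`` from a pipe-separated lineage string."""
    try:
        prefix = RANK_PREFIXES[rank]
    except KeyError:
        raise ValueError(f"unknown rank {rank!r}; valid: {sorted(RANK_PREFIXES)}")
    for part in str(lineage).split("|"):
        if part.startswith(prefix):
            return part[len(prefix):]
    return None


def aggregate_level(table: TaxonAbundanceTable, rank: str) -> TaxonAbundanceTable:
    """Sum abundances within the requested taxonomic rank.

    Rows whose lineage lacks the rank are dropped (they carry no name at
    that level); per-sample totals among parseable rows are preserved.
    """
    names = [parse_rank(lin, rank) for lin in table.taxa]
    keep = [n is not None for n in names]
    if not any(keep):
        raise ValueError(f"no lineage parseable at rank {rank!r}")
    sub = table.abundances.loc[keep].copy()
    sub.index = pd.Index([n for n in names if n is not None], name=rank)
    agg = sub.groupby(level=0, sort=False).sum()
    return TaxonAbundanceTable(agg, unit=table.unit)


def lump_rare(
    table: TaxonAbundanceTable,
    ann: SampleAnnotation | None = None,
    threshold_percent: float = 1.0,
    per_sample: bool = False,
) -> TaxonAbundanceTable:
    """Collapse low-abundance taxa into a single "Under 1%" row.

    Default rule: a taxon is lumped when its mean abundance is below the
    threshold within *each* comparison group (requires ``ann``); with
    ``per_sample=True`` (or without annotation) the mean over all samples is
    used instead.  Per-sample totals are conserved exactly.
    """
    pct = table.to_percent()
    ab = pct.abundances
    if per_sample or ann is None:
        low = ab.mean(axis=1) < threshold_percent
    else:
        low = pd.Series(True, index=ab.index)
        for group in ("patient", "control"):
            ids = [s for s in ann.samples_in(group=group) if s in ab.columns]
            if ids:
                low &= ab[ids].mean(axis=1) < threshold_percent
    retained = ab.loc[~low]
    lumped = ab.loc[low].sum(axis=0)
    out = pd.concat([retained, lumped.to_frame(UNDER_LABEL).T])
    out.index.name = ab.index.name
    result = TaxonAbundanceTable(out, unit="percent")
    return result if table.unit == "percent" else result.to_fraction()


def _group_values(values: pd.Series, ann: SampleAnnotation) -> tuple[np.ndarray, np.ndarray]:
    pat = [s for s in ann.samples_in(group="patient") if s in values.index]
    ctl = [s for s in ann.samples_in(group="control") if s in values.index]
    return values[pat].to_numpy(), values[ctl].to_numpy()


def diversity_compare(table: TaxonAbundanceTable, ann: SampleAnnotation) -> GroupComparisonResult:
    """Per-sample Shannon index, then Welch's t between patients and controls."""
    h = pd.Series(
        {s: shannon_index(table.abundances[s].to_numpy()) for s in table.sample_ids}
    )
    xp, xc = _group_values(h, ann)
    if len(xp) < 2 or len(xc) < 2:
        raise ValueError("need >= 2 samples per group")
    t, df, p = welch_t_test(two_sample_summary(xc, xp))  # sign: patient - control
    return GroupComparisonResult(
        statistic_name="welch_t_shannon",
        statistic=t,
        p_value=p,
        group_summaries={
            "patient": {"n": len(xp), "mean_shannon": float(xp.mean())},
            "control": {"n": len(xc), "mean_shannon": float(xc.mean())},
        },
        metadata={"df": df, "per_sample_shannon": h.to_dict()},
    )


def presence_absence_test(
    table: TaxonAbundanceTable,
    ann: SampleAnnotation,
    taxon: str,
    detection_threshold: float = 0.0,
) -> GroupComparisonResult:
    """Fisher's exact test of group association with taxon presence.

    A sample is positive when the taxon's abundance exceeds
    ``detection_threshold`` (default: any nonzero abundance).  ``taxon`` may
    be a full lineage string or a name matched at any rank.
    """
    if taxon in table.taxa:
        row = table.abundances.loc[taxon]
    else:
        hits = [lin for lin in table.taxa
                if taxon in {parse_rank(lin, r) for r in RANK_PREFIXES}]
        if not hits:
            raise ValueError(f"taxon {taxon!r} not found in table")
        row = table.abundances.loc[hits].sum(axis=0)

    positive = row > detection_threshold
    xp, xc = _group_values(positive, ann)
    ct = ContingencyTable2x2(
        a=int(xp.sum()), b=int(len(xp) - xp.sum()),
        c=int(xc.sum()), d=int(len(xc) - xc.sum()),
    )
    p = fisher_exact_2x2(ct)
    return GroupComparisonResult(
        statistic_name="fisher_exact_presence",
        statistic=float("nan"),
        p_value=p,
        group_summaries={
            "patient": {"positive": ct.a, "negative": ct.b},
            "control": {"positive": ct.c, "negative": ct.d},
        },
        metadata={"taxon": taxon, "detection_threshold": detection_threshold},
    )


def community_comparison(
    table: TaxonAbundanceTable,
    ann: SampleAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
    distance: str = "euclidean",
) -> tuple[dict, PermanovaResult]:
    """PCA on feature-scaled abundances plus PERMANOVA on sample distances.

    Default distance is Euclidean on the scaled (z-scored) abundance matrix,
    matching the ordination; ``distance='braycurtis'`` uses Bray-Curtis on
    the raw relative abundances instead.
    """
    if table.abundances.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = table.abundances.T.to_numpy()  # samples x taxa
    sample_ids = list(table.sample_ids)
    labels = ann.table.loc[sample_ids, "group"].to_numpy()

    scores, loadings, evr = pca(X, scale=True)

    if distance == "euclidean":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        diff = Z[:, None, :] - Z[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif distance == "braycurtis":
        num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            D = np.where(den > 0, num / den, 0.0)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError("distance must be 'euclidean' or 'braycurtis'")

    perma = permanova(D, labels, n_perm=n_perm, seed=seed)
    ordination = {
        "scores": pd.DataFrame(
            scores[:, : min(5, scores.shape[1])], index=sample_ids,
            columns=[f"PC{i + 1}" for i in range(min(5, scores.shape[1]))],
        ),
        "explained_variance_ratio": evr,
        "distance": distance,
    }
    return ordination, perma
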