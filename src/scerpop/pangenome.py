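"""Pan-genome gene content: presence/absence calling from alignment
evidence, rarity filtering, Venn partitions, group-majority and
lineage-specific gene detection, and gene-content PCA.

An ORF counts as present in an isolate when some alignment record reaches
both the identity (default >= 95%) and coverage (aligned length / catalog
ORF length, default >= 0.75, capped at 1) thresholds; both boundaries are
inclusive and configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import PopulationMap, new_presence_matrix

logger = logging.getLogger(__name__)


def _qualifying(records: pd.DataFrame, query_lengths: dict[str, int], id_min: float, cov_min: float) -> pd.Series:
    qlen = records["qseqid"].map(query_lengths)
    if qlen.isna().any():
        bad = sorted(records.loc[qlen.isna(), "qseqid"].unique())
        raise ValueError(f"alignment records reference unknown ORFs: {bad[:5]}")
    coverage = np.minimum(records["length"] / qlen, 1.0)
    return (records["pident"] >= id_min) & (coverage >= cov_min)


def call_orf_presence(
    records: pd.DataFrame,
    query_lengths: dict[str, int],
    isolates: list[str],
    id_min: float = 95.0,
    cov_min: float = 0.75,
) -> pd.DataFrame:
    """Presence matrix from alignment records (``isolate``/``qseqid`` rows).

    ``query_lengths`` maps catalog ORF ids to their length (the coverage
    denominator).  ORFs with no qualifying record in an isolate — including
    no record at all — are absent.
    """
    unknown_iso = set(map(str, records["isolate"].unique())) - set(map(str, isolates))
    if unknown_iso:
        raise ValueError(f"alignment records reference unknown isolates: {sorted(unknown_iso)[:5]}")
    ok = _qualifying(records, query_lengths, id_min, cov_min)
    hits = records.loc[ok, ["isolate", "qseqid"]].drop_duplicates()
    pm_mat = new_presence_matrix(isolates, list(query_lengths))
    if not hits.empty:
        pm_mat.values[
            pm_mat.index.get_indexer(hits["isolate"].astype(str)),
            pm_mat.columns.get_indexer(hits["qseqid"]),
        ] = True
    return pm_mat


def classify_novel_orfs(
    predicted_records: pd.DataFrame,
    predicted_ids: list[str],
    known_orf_ids,
    query_lengths: dict[str, int],
    id_min: float = 95.0,
    cov_min: float = 0.75,
) -> tuple[set[str], dict[str, str]]:
    """Split predicted ORFs into novel ids and known-id assignments.

    A predicted ORF matching no known catalog ORF at the presence thresholds
    is novel; a match collapses onto the (best-scoring) known id.
    """
    known = set(known_orf_ids)
    recs = predicted_records[predicted_records["sseqid"].isin(known)].copy()
    ok = _qualifying(recs, query_lengths, id_min, cov_min)
    hits = recs[ok].sort_values("bitscore", ascending=False, kind="stable")
    assignment: dict[str, str] = {}
    for row in hits.itertuples():
        assignment.setdefault(row.qseqid, row.sseqid)  # best hit wins
    novel = {q for q in predicted_ids if q not in assignment}
    return novel, assignment


def rarity_filter(pm_mat: pd.DataFrame, min_frac: float = 0.01) -> pd.DataFrame:
    """Keep ORFs present in at least ``min_frac`` of all isolates."""
    if pm_mat.empty:
        raise ValueError("empty presence matrix")
    frac = pm_mat.mean(axis=0)
    kept = pm_mat.loc[:, frac >= min_frac]
    logger.info("rarity_filter: %d ORFs in, %d out", pm_mat.shape[1], kept.shape[1])
    return kept


def venn_partition(
    pm_mat: pd.DataFrame, pm: PopulationMap, groups: list[str] | None = None
) -> dict[tuple[str, ...], set[str]]:
    """All regions of the k-set Venn partition of group gene content.

    An ORF occurs in a group iff present in >= 1 of its isolates.  Region
    keys are sorted tuples of the groups sharing the region; every
    non-empty combination is returned (7 regions for three groups).
    """
    groups = groups or pm.groups
    outside = set(pm_mat.index) - {
        iso for g in groups for iso in pm.members("group", g)
    }
    if outside:
        logger.warning("venn_partition: %d isolates outside listed groups excluded", len(outside))
    occurs = {}
    for g in groups:
        rows = [iso for iso in pm.members("group", g) if iso in pm_mat.index]
        occurs[g] = set(pm_mat.columns[pm_mat.loc[rows].any(axis=0)])
    regions: dict[tuple[str, ...], set[str]] = {}
    from itertools import combinations

    for k in range(1, len(groups) + 1):
        for combo in combinations(groups, k):
            inside = set.intersection(*(occurs[g] for g in combo))
            for g in groups:
                if g not in combo:
                    inside -= occurs[g]
            regions[tuple(sorted(combo))] = inside
    return regions


def group_majority_genes(
    pm_mat: pd.DataFrame,
    pm: PopulationMap,
    group_hi: str,
    group_lo: str,
    hi: float = 0.90,
    lo: float = 0.10,
) -> set[str]:
    """ORFs carried by > hi of one group's isolates and < lo of another's.

    Both inequalities are strict, matching the >90% / <10% rule.
    """
    rows_hi = [i for i in pm.members("group", group_hi) if i in pm_mat.index]
    rows_lo = [i for i in pm.members("group", group_lo) if i in pm_mat.index]
    if not rows_hi or not rows_lo:
        raise ValueError("both groups must have isolates in the presence matrix")
    frac_hi = pm_mat.loc[rows_hi].mean(axis=0)
    frac_lo = pm_mat.loc[rows_lo].mean(axis=0)
    return set(pm_mat.columns[(frac_hi > hi) & (frac_lo < lo)])


def lineage_specific_genes(pm_mat: pd.DataFrame, pm: PopulationMap) -> dict[str, set[str]]:
    """ORFs present in >= 1 isolate of exactly one lineage and zero of all others."""
    missing = set(pm_mat.index) - set(pm.isolates)
    if missing:
        raise ValueError(f"isolates without lineage assignment: {sorted(missing)[:5]}")
    counts = {}
    for lin in pm.lineages:
        rows = [i for i in pm.members("lineage", lin) if i in pm_mat.index]
        counts[lin] = pm_mat.loc[rows].any(axis=0) if rows else pd.Series(False, index=pm_mat.columns)
    occ = pd.DataFrame(counts)
    n_lineages = occ.sum(axis=1)
    out = {}
    for lin in pm.lineages:
        out[lin] = set(occ.index[(n_lineages == 1) & occ[lin]])
    return out


def embed_presence(pm_mat: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centred boolean presence matrix; deterministic up to sign."""
    if pm_mat.shape[1] < 2:
        raise ValueError("need at least 2 ORFs to embed")
    X = pm_mat.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    df = pd.DataFrame(coords, index=pm_mat.index, columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return df, pca.explained_variance_
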