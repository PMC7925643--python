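"""Heterozygosity ratios, nucleotide diversity (pi), Watterson's theta, and
the SNP-matrix PCA.

pi is the average number of pairwise nucleotide differences per surveyed
genomic site and theta the segregating-site count scaled by the harmonic
number of the sample size; both are normalised by a user-supplied surveyed
genome length, since per-SNP values would be orders of magnitude larger
than the per-genomic-site quantities usually reported for yeast.

Diploid isolates contribute two alleles per site; a heterozygote
contributes one of each.  Group-level statistics only use sites where at
least ``min_frac`` (default 80%) of the group's isolates are genotyped, and
theta's harmonic number uses that fixed minimum sample size ("NumNuc")
rather than the per-site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix, PopulationMap

#: surveyed genome length of the S288c reference, the default denominator
S288C_GENOME_LENGTH = 12_071_326


@dataclass
class DiversityResult:
    label: str
    pi: float
    theta: float
    n_sites_used: int
    numnuc: int  # minimum isolates with data per site
    genome_length: int


def het_ratio(gm: GenotypeMatrix, consensus_sizes: dict[str, int]) -> pd.DataFrame:
    """Per-isolate heterozygous-site count over consensus genome size.

    The consensus genome size is the callable genome of the isolate; the
    ratio is the heterozygosity statistic reported per isolate.
    """
    missing = [iso for iso in gm.isolates if iso not in consensus_sizes]
    if missing:
        raise ValueError(f"no consensus genome size for isolates: {missing[:5]}")
    sizes = np.array([consensus_sizes[iso] for iso in gm.isolates], dtype=float)
    if (sizes <= 0).any():
        raise ValueError("consensus genome sizes must be positive")
    counts = (gm.dosages == 1).sum(axis=0)
    return pd.DataFrame(
        {
            "isolate": gm.isolates,
            "het_site_count": counts,
            "consensus_genome_size": sizes.astype(int),
            "het_ratio": counts / sizes,
        }
    )


def group_site_mask(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str,
    min_frac: float = 0.8,
    level: str = "group",
) -> np.ndarray:
    """Boolean site mask: >= min_frac of the group's isolates genotyped."""
    members = pm.members(level, group)
    cols = gm.isolate_index(members)
    called = (gm.dosages[:, cols] != -1).sum(axis=1)
    return called >= min_frac * len(members)


def nucleotide_diversity(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str,
    genome_length: int = S288C_GENOME_LENGTH,
    min_frac: float = 0.8,
    level: str = "group",
) -> DiversityResult:
    """pi and Watterson's theta for one population/group/lineage.

    Per masked site with n called alleles and alt count k, the site
    heterozygosity is h = k(n-k)/C(n,2); pi = sum(h)/L.  theta = S/(a*L)
    with S the masked polymorphic-site count and a the harmonic number
    sum_{i<n0} 1/i at the group's fixed NumNuc allele count n0.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    members = pm.members(level, group)
    numnuc = int(np.ceil(min_frac * len(members)))
    mask = group_site_mask(gm, pm, group, min_frac=min_frac, level=level)
    cols = gm.isolate_index(members)
    sub = gm.dosages[np.ix_(np.flatnonzero(mask), cols)]
    called = sub != -1
    n = 2 * called.sum(axis=1)
    k = np.where(called, sub, 0).sum(axis=1)
    usable = n >= 2
    n, k = n[usable], k[usable]
    pairs = n * (n - 1) / 2.0
    h = k * (n - k) / pairs
    pi = float(h.sum()) / genome_length
    segregating = int(((k > 0) & (k < n)).sum())
    n0 = 2 * numnuc
    a_n = float(np.sum(1.0 / np.arange(1, n0))) if n0 >= 2 else np.nan
    theta = segregating / (a_n * genome_length) if n0 >= 2 else float("nan")
    return DiversityResult(
        label=group,
        pi=pi,
        theta=theta,
        n_sites_used=int(usable.sum()),
        numnuc=numnuc,
        genome_length=genome_length,
    )


def diversity_table(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    genome_length: int = S288C_GENOME_LENGTH,
    min_frac: float = 0.8,
    levels: tuple[str, ...] = ("population", "group", "lineage"),
) -> pd.DataFrame:
    """pi/theta for every population, group and lineage (one row each)."""
    rows = []
    for level in levels:
        for name in sorted(pm.table[level].unique()):
            r = nucleotide_diversity(gm, pm, name, genome_length, min_frac, level=level)
            rows.append((level, r.label, r.pi, r.theta, r.n_sites_used, r.numnuc))
    return pd.DataFrame(rows, columns=["level", "label", "pi", "theta", "n_sites_used", "numnuc"])


def snp_pca(gm: GenotypeMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the mean-centred alt-dosage matrix (isolates as observations).

    Missing dosages are imputed to the site mean.  Deterministic up to the
    sign of each component.  Returns (coordinates, explained variances).
    """
    if gm.n_sites < 2:
        raise ValueError("PCA needs at least 2 sites")
    X = gm.dosages.astype(float).T  # isolates x sites
    X[X == -1] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords, index=gm.isolates, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return df, pca.explained_variance_
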