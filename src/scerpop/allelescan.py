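"""Group-specific allele detection on a subsampled SNP set.

The scan follows a fixed order: drop sites whose non-reference allele is
carried by fewer than 1% of isolates, randomly subsample a fixed number of
sites, drop sites genotyped in fewer than 80% of any lineage's isolates,
then report alleles carried by more than 90% of the genotyped isolates of
one domesticated group but by at most 90% of the other's.  "Carrying" an
allele means having at least one copy, so a heterozygote carries both.
Detected sites are mapped onto gene intervals for enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class AlleleScanParams:
    share_min: float = 0.01
    subsample_n: int = 10_000
    lineage_presence_min: float = 0.80
    group_hi: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("share_min", "lineage_presence_min", "group_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def sharing_filter(gm: GenotypeMatrix, p: AlleleScanParams | None = None) -> GenotypeMatrix:
    """Keep sites whose alt allele is carried by >= share_min of all isolates."""
    p = p or AlleleScanParams()
    carriers = (gm.dosages >= 1).sum(axis=1)
    keep = carriers >= p.share_min * gm.n_isolates
    return gm.take_sites(keep)


def subsample_sites(gm: GenotypeMatrix, p: AlleleScanParams | None = None) -> GenotypeMatrix:
    """Uniform site subsample without replacement, original order preserved."""
    p = p or AlleleScanParams()
    if gm.n_sites < p.subsample_n:
        raise ValueError(
            f"cannot subsample {p.subsample_n} sites from {gm.n_sites} available"
        )
    rng = np.random.default_rng(int(p.seed) & 0x7FFFFFFF)
    chosen = np.sort(rng.choice(gm.n_sites, size=p.subsample_n, replace=False))
    return gm.take_sites(chosen)


def lineage_presence_filter(
    gm: GenotypeMatrix, pm: PopulationMap, p: AlleleScanParams | None = None
) -> GenotypeMatrix:
    """Keep sites genotyped in >= lineage_presence_min of EVERY lineage."""
    p = p or AlleleScanParams()
    keep = np.ones(gm.n_sites, dtype=bool)
    for lin in pm.lineages:
        cols = gm.isolate_index(pm.members("lineage", lin))
        called = (gm.dosages[:, cols] != MISSING).sum(axis=1)
        keep &= called >= p.lineage_presence_min * cols.size
    return gm.take_sites(keep)


def _carrier_fractions(gm: GenotypeMatrix, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ref-carrier, alt-carrier) fraction per site over genotyped isolates."""
    sub = gm.dosages[:, cols]
    called = sub != MISSING
    n = called.sum(axis=1)
    ref_car = (called & (sub <= 1)).sum(axis=1)
    alt_car = (called & (sub >= 1)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(n > 0, ref_car / np.maximum(n, 1), 0.0)
        fa = np.where(n > 0, alt_car / np.maximum(n, 1), 0.0)
    return fr, fa


def group_specific_alleles(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group_a: str,
    group_b: str,
    p: AlleleScanParams | None = None,
) -> pd.DataFrame:
    """Alleles carried by > group_hi of one group but <= group_hi of the other.

    Returns a long table (chrom, pos, allele, base, group, fraction_a,
    fraction_b), one row per specific allele.
    """
    p = p or AlleleScanParams()
    cols_a = gm.isolate_index(pm.members("group", group_a))
    cols_b = gm.isolate_index(pm.members("group", group_b))
    fr_a, fa_a = _carrier_fractions(gm, cols_a)
    fr_b, fa_b = _carrier_fractions(gm, cols_b)
    rows = []
    for allele, (fx_a, fx_b) in {"ref": (fr_a, fr_b), "alt": (fa_a, fa_b)}.items():
        base = gm.sites[allele].to_numpy()
        a_specific = (fx_a > p.group_hi) & (fx_b <= p.group_hi)
        b_specific = (fx_b > p.group_hi) & (fx_a <= p.group_hi)
        for mask, grp in ((a_specific, group_a), (b_specific, group_b)):
            for i in np.flatnonzero(mask):
                rows.append(
                    (
                        gm.sites["chrom"].iat[i],
                        int(gm.sites["pos"].iat[i]),
                        allele,
                        base[i],
                        grp,
                        float(fx_a[i]),
                        float(fx_b[i]),
                    )
                )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "allele", "base", "group", "fraction_a", "fraction_b"]
    )
    return out.sort_values(["chrom", "pos", "allele"], ignore_index=True)


def map_snps_to_genes(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map 1-based SNP positions onto half-open 0-based gene intervals.

    A SNP at ``pos`` falls in a gene iff ``pos - 1`` is in [start, end); a
    site may map to several overlapping genes.  Unmapped sites get a row
    with gene NaN.
    """
    if ((genes["start"] < 0) | (genes["start"] >= genes["end"])).any():
        raise ValueError("malformed gene interval (need 0 <= start < end)")
    rows = []
    for chrom, sub_sites in sites.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        names = g["name"].to_numpy()
        for pos in sub_sites["pos"]:
            hit = (starts <= pos - 1) & (pos - 1 < ends)
            if hit.any():
                for name in names[hit]:
                    rows.append((chrom, int(pos), name))
            else:
                rows.append((chrom, int(pos), np.nan))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene"])


def run_allele_scan(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group_a: str,
    group_b: str,
    genes: pd.DataFrame | None = None,
    p: AlleleScanParams | None = None,
) -> pd.DataFrame:
    """Full scan in the prescribed order: share -> subsample -> lineage
    presence -> detection (-> gene mapping when intervals are given)."""
    p = p or AlleleScanParams()
    gm = sharing_filter(gm, p)
    gm = subsample_sites(gm, p)
    gm = lineage_presence_filter(gm, pm, p)
    hits = group_specific_alleles(gm, pm, group_a, group_b, p)
    if genes is not None and not hits.empty:
        mapping = map_snps_to_genes(hits[["chrom", "pos"]].drop_duplicates(), genes)
        mapped = (
            mapping.dropna(subset=["gene"])
            .groupby(["chrom", "pos"])["gene"]
            .agg(lambda g: ",".join(sorted(g)))
            .rename("genes")
        )
        hits = hits.merge(mapped, on=["chrom", "pos"], how="left")
    return hits
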