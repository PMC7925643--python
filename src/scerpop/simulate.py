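"""Synthetic cohorts with planted wild/domesticated structure.

The generator emulates the study design every downstream stage expects: a
near-homozygous wild population, two domesticated groups (liquid-state and
solid-state fermentation, LSF/SSF) with elevated heterozygosity, lineage
substructure inside each group, planted group-specific and lineage-specific
SNP alleles and ORF content, per-site read support from two callers, and
uniform missingness.

Design choices that matter downstream:

* Sites are independent (no linkage); ``ld_block_size > 1`` switches on a
  block-copy mode that duplicates allele patterns in windows so LD pruning
  has something to prune.
* Background (non-planted) sites realise their per-group carrier counts
  exactly from frequencies clipped to [0.2, 0.8], so only planted sites can
  satisfy the >90% group-specific carrier rule; lineage structure comes from
  Dirichlet-weighted carrier assignment within each group.
* Heterozygosity is planted by flipping homozygous genotypes to het at the
  per-population rate scaled by genome length — the statistic the pipeline
  measures — not by a mating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    new_presence_matrix,
)

_BASES = np.array(list("ACGT"))

DEFAULT_LINEAGES: list[tuple[str, str, str]] = [
    # wild forest lineages
    ("CHN-IX", "Wild", "Wild"),
    ("CHN-I", "Wild", "Wild"),
    ("FarEastAsia", "Wild", "Wild"),
    ("NorthAmericanOak", "Wild", "Wild"),
    # liquid-state fermentation
    ("Wine", "LSF", "Domesticated"),
    ("Beer", "LSF", "Domesticated"),
    ("Milk", "LSF", "Domesticated"),
    ("HoneyWine", "LSF", "Domesticated"),
    # solid-state fermentation
    ("Mantou", "SSF", "Domesticated"),
    ("Baijiu", "SSF", "Domesticated"),
    ("Huangjiu", "SSF", "Domesticated"),
    ("Sake", "SSF", "Domesticated"),
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of the real study scaled to desk size:
    heterozygous-site ratios of 0.005% (wild) and 0.143% (domesticated) of
    the surveyed genome, sequencing depth around 184x, three groups of four
    lineages with ten isolates each.
    """

    n_isolates_per_lineage: int = 10
    lineages: list[tuple[str, str, str]] = field(default_factory=lambda: list(DEFAULT_LINEAGES))
    n_sites: int = 5000
    genome_length: int = 45_000
    het_rate_wild: float = 0.00005
    het_rate_domesticated: float = 0.00143
    n_group_specific_sites: int = 50
    n_lineage_specific_sites: int = 5
    missing_rate: float = 0.02
    n_orfs: int = 500
    n_group_specific_orfs: int = 10
    n_lineage_specific_orfs: int = 2
    n_rare_orfs: int = 5
    n_novel_orfs: int = 5
    orf_length_range: tuple[int, int] = (300, 3000)
    mean_depth: float = 184.0
    depth_dispersion: float = 30.0
    base_error_rate: float = 0.002
    ld_block_size: int = 1
    wild_population: str = "Wild"
    seed: int = 0

    # frequency model for background sites (see module docstring)
    background_freq_bounds: tuple[float, float] = (0.2, 0.8)
    group_divergence_sd: float = 0.25
    lineage_dirichlet_alpha: float = 1.5

    def __post_init__(self) -> None:
        for name in ("het_rate_wild", "het_rate_domesticated", "missing_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_isolates_per_lineage", "n_sites", "genome_length", "n_orfs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sites > self.genome_length:
            raise ValueError("n_sites exceeds genome_length")
        groups = {}
        for lin, grp, pop in self.lineages:
            if lin in groups and groups[lin] != grp:
                raise ValueError(f"lineage {lin} mapped to multiple groups")
            groups[lin] = grp
        if len({lin for lin, _, _ in self.lineages}) != len(self.lineages):
            raise ValueError("duplicate lineage names")
        planted = (
            self.n_group_specific_sites * len(self.domesticated_groups())
            + self.n_lineage_specific_sites * len(self.lineages)
        )
        if planted > self.n_sites:
            raise ValueError(
                f"{planted} planted sites exceed n_sites={self.n_sites}"
            )
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def groups(self) -> list[str]:
        out = []
        for _, grp, _ in self.lineages:
            if grp not in out:
                out.append(grp)
        return out

    def domesticated_groups(self) -> list[str]:
        out = []
        for _, grp, pop in self.lineages:
            if pop != self.wild_population and grp not in out:
                out.append(grp)
        return out


@dataclass
class TruthTables:
    """Ground truth for recovery tests; keys always exist in the emitted data."""

    planted_group_specific_sites: dict[tuple[str, int], str] = field(default_factory=dict)
    planted_lineage_specific_sites: dict[tuple[str, int], str] = field(default_factory=dict)
    planted_group_specific_orfs: dict[str, str] = field(default_factory=dict)
    planted_lineage_specific_orfs: dict[str, str] = field(default_factory=dict)
    planted_novel_orfs: set[str] = field(default_factory=set)
    true_presence: pd.DataFrame | None = None
    true_het_counts: dict[str, int] = field(default_factory=dict)
    consensus_sizes: dict[str, int] = field(default_factory=dict)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *stream]))


def _sample_sheet(config: SimulationConfig) -> PopulationMap:
    rows = []
    for lin, grp, pop in config.lineages:
        for i in range(config.n_isolates_per_lineage):
            rows.append((f"{lin}_{i + 1:02d}", pop, grp, lin))
    return PopulationMap(pd.DataFrame(rows, columns=["isolate", "population", "group", "lineage"]))


def simulate_population(config: SimulationConfig) -> tuple[GenotypeMatrix, PopulationMap, TruthTables]:
    """Genotype matrix + sample sheet + truth for a planted-structure cohort."""
    rng = _rng(config, 0)
    pm = _sample_sheet(config)
    isolates = pm.isolates
    n_iso = len(isolates)
    lineage_of = pm.table["lineage"].to_numpy()
    group_of = pm.table["group"].to_numpy()
    pop_of = pm.table["population"].to_numpy()
    groups = config.groups()
    dom_groups = config.domesticated_groups()
    lineage_names = [lin for lin, _, _ in config.lineages]

    positions = np.sort(rng.choice(config.genome_length, size=config.n_sites, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    sites = pd.DataFrame(
        {
            "chrom": "chrI",
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    # --- partition sites into planted and background -----------------------
    n_gs = config.n_group_specific_sites * len(dom_groups)
    n_ls = config.n_lineage_specific_sites * len(config.lineages)
    planted_idx = rng.choice(config.n_sites, size=n_gs + n_ls, replace=False)
    gs_idx = planted_idx[:n_gs].reshape(len(dom_groups), -1)
    ls_idx = planted_idx[n_gs:].reshape(len(config.lineages), -1)
    background = np.setdiff1d(np.arange(config.n_sites), planted_idx)

    dosages = np.zeros((config.n_sites, n_iso), dtype=np.int8)

    # --- background: clipped hierarchical carrier model --------------------
    n_bg = background.size
    lo, hi = config.background_freq_bounds
    p0 = rng.uniform(0.3, 0.7, size=n_bg)
    for grp in groups:
        cols = np.flatnonzero(group_of == grp)
        grp_lineages = [lin for lin, g, _ in config.lineages if g == grp]
        f = np.clip(p0 + rng.normal(0.0, config.group_divergence_sd, size=n_bg), lo, hi)
        counts = np.rint(f * cols.size).astype(int)
        # Dirichlet lineage weights + Gumbel top-k = weighted sampling
        # without replacement of exactly `counts` carriers per site
        w_lin = rng.dirichlet(
            np.full(len(grp_lineages), config.lineage_dirichlet_alpha), size=n_bg
        )
        lin_pos = {lin: k for k, lin in enumerate(grp_lineages)}
        col_lin = np.array([lin_pos[lineage_of[c]] for c in cols])
        w_iso = w_lin[:, col_lin]  # (n_bg, n_cols)
        keys = np.log(w_iso) + rng.gumbel(size=w_iso.shape)
        ranks = np.argsort(np.argsort(-keys, axis=1), axis=1)
        carrier = ranks < counts[:, None]
        block = dosages[background][:, cols]
        block[carrier] = 2
        rows = background[:, None]
        dosages[rows, cols[None, :]] = block

    # optional linkage: copy each block leader's pattern across its block
    if config.ld_block_size > 1:
        for start in range(0, n_bg, config.ld_block_size):
            blk = background[start : start + config.ld_block_size]
            dosages[blk] = dosages[blk[0]]

    truth = TruthTables()

    # --- planted group-specific sites --------------------------------------
    for gi, grp in enumerate(dom_groups):
        own = np.flatnonzero(group_of == grp)
        n_own_carriers = int(np.ceil(0.95 * own.size))
        for site in gs_idx[gi]:
            dosages[site, :] = 0
            carriers = rng.choice(own, size=n_own_carriers, replace=False)
            dosages[site, carriers] = 2
            for other in groups:
                if other == grp:
                    continue
                cols = np.flatnonzero(group_of == other)
                k = int(round(0.3 * cols.size))
                dosages[site, rng.choice(cols, size=k, replace=False)] = 2
            key = ("chrI", int(positions[site]))
            truth.planted_group_specific_sites[key] = grp

    # --- planted lineage-specific sites -------------------------------------
    # low within-lineage frequency: high-frequency exclusive alleles would
    # make the *reference* allele group-specific between the domesticated
    # groups, conflating the two planted signals
    for li, lin in enumerate(lineage_names):
        own = np.flatnonzero(lineage_of == lin)
        k = int(np.ceil(0.3 * own.size))
        for site in ls_idx[li]:
            dosages[site, :] = 0
            dosages[site, rng.choice(own, size=k, replace=False)] = 2
            truth.planted_lineage_specific_sites[("chrI", int(positions[site]))] = lin

    # --- heterozygosity: flip hom genotypes to het at population rates ------
    wild = pop_of == config.wild_population
    rates = np.where(wild, config.het_rate_wild, config.het_rate_domesticated)
    for j in range(n_iso):
        k = int(rng.binomial(config.genome_length, rates[j]))
        k = min(k, config.n_sites)
        het_sites = rng.choice(config.n_sites, size=k, replace=False)
        dosages[het_sites, j] = 1
        truth.true_het_counts[isolates[j]] = k

    # --- uniform missingness -------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    # the consensus genome of an isolate excludes uncallable positions
    cons = int(round(config.genome_length * (1.0 - config.missing_rate)))
    truth.consensus_sizes = {iso: cons for iso in isolates}

    gm = GenotypeMatrix(sites=sites, isolates=isolates, dosages=dosages)
    return gm, pm, truth


# ---------------------------------------------------------------------------
# read support


def simulate_read_support(
    gm: GenotypeMatrix, config: SimulationConfig, caller_id: str = "A"
) -> pd.DataFrame:
    """Per isolate x site read support consistent with the genotype matrix.

    Depth is negative-binomial around ``mean_depth`` (variance
    ``mu + mu^2/dispersion``); ref/alt read splits are binomial given the
    genotype, with sequencing errors flipping reads to the other allele at
    ``base_error_rate``.  Missing genotypes get zero depth.  The caller id
    enters the random stream, so callers "A" and "B" share genotypes but not
    depths — the shape of a two-caller consensus input.
    """
    if gm.n_sites == 0 or gm.n_isolates == 0:
        raise ValueError("empty genotype matrix")
    rng = _rng(config, 1, sum(ord(c) for c in caller_id))
    n_sites, n_iso = gm.dosages.shape
    mu, k = config.mean_depth, config.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + mu), size=(n_sites, n_iso)).astype(np.int64)
    dos = gm.dosages
    err = config.base_error_rate
    alt = np.zeros_like(depth)
    hom_ref = dos == 0
    hom_alt = dos == 2
    het = dos == 1
    alt[hom_ref] = rng.binomial(depth[hom_ref], err)
    alt[hom_alt] = depth[hom_alt] - rng.binomial(depth[hom_alt], err)
    alt[het] = rng.binomial(depth[het], 0.5)
    miss = dos == MISSING
    depth[miss] = 0
    alt[miss] = 0
    ref = depth - alt

    gt_label = np.empty(dos.shape, dtype=object)
    gt_label[hom_ref] = GT_HOM_REF
    gt_label[het] = GT_HET
    gt_label[hom_alt] = GT_HOM_ALT
    gt_label[miss] = GT_MISSING

    iso_arr = np.repeat(gm.isolates, n_sites)
    calls = pd.DataFrame(
        {
            "isolate": pd.Categorical(iso_arr),
            "chrom": np.tile(gm.sites["chrom"].to_numpy(), n_iso),
            "pos": np.tile(gm.sites["pos"].to_numpy(), n_iso),
            "depth": depth.T.ravel(),
            "ref_reads": ref.T.ravel(),
            "alt_reads": alt.T.ravel(),
            "genotype": gt_label.T.ravel(),
            "caller_id": caller_id,
        }
    )
    return calls


# ---------------------------------------------------------------------------
# ORF catalog, alignments, gene intervals, annotations


@dataclass
class OrfSimulation:
    """Everything the pan-genome stages consume, plus ground truth."""

    catalog: dict[str, str]
    alignments: pd.DataFrame  # isolate assemblies vs. catalog, + isolate column
    predicted_ids: list[str]
    predicted_alignments: pd.DataFrame  # gene-prediction output vs. catalog
    predicted_lengths: dict[str, int]  # coverage denominators for predicted ORFs
    truth: TruthTables


def _random_seqs(rng: np.random.Generator, names: list[str], length_range: tuple[int, int]) -> dict[str, str]:
    lo, hi = length_range
    out = {}
    for name in names:
        n = int(rng.integers(lo, hi + 1))
        out[name] = "".join(_BASES[rng.integers(0, 4, size=n)])
    return out


def _alignment_rows(rng, rows, qlens):
    """Assemble 12-column records given (qseqid, sseqid, present) triples."""
    recs = []
    for qseqid, sseqid, present in rows:
        qlen = qlens[qseqid]
        if present:
            pident = rng.uniform(97.0, 100.0)
            length = int(np.ceil(rng.uniform(0.90, 1.0) * qlen))
        else:
            pident = rng.uniform(70.0, 90.0)
            length = int(np.ceil(rng.uniform(0.30, 0.70) * qlen))
        mismatch = int(round(length * (100.0 - pident) / 100.0))
        recs.append(
            (qseqid, sseqid, round(pident, 2), length, mismatch, 0,
             1, length, 1, length, 1e-30, round(2.0 * length, 1))
        )
    return pd.DataFrame(recs, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])


def simulate_orf_catalog(
    config: SimulationConfig, pm: PopulationMap, truth: TruthTables | None = None
) -> OrfSimulation:
    """ORF catalog + per-isolate alignment evidence encoding planted presence.

    Present ORFs get records with identity >= 97% and coverage >= 90% of the
    catalog ORF length; absent ORFs get either no record or a decoy record
    below both thresholds.
    """
    if not pm.isolates:
        raise ValueError("empty population map")
    rng = _rng(config, 2)
    truth = truth if truth is not None else TruthTables()
    isolates = pm.isolates
    n_iso = len(isolates)
    group_of = pm.table["group"].to_numpy()
    lineage_of = pm.table["lineage"].to_numpy()
    groups = config.groups()
    lineage_names = [lin for lin, _, _ in config.lineages]

    orf_ids = [f"ORF{i + 1:05d}" for i in range(config.n_orfs)]
    catalog = _random_seqs(rng, orf_ids, config.orf_length_range)

    n_special = (
        config.n_group_specific_orfs * len(groups)
        + config.n_lineage_specific_orfs * len(lineage_names)
        + config.n_rare_orfs
    )
    if n_special > config.n_orfs:
        raise ValueError("planted ORFs exceed n_orfs")
    special = rng.choice(config.n_orfs, size=n_special, replace=False)
    cursor = 0

    presence = np.ones((n_iso, config.n_orfs), dtype=bool)

    for grp in groups:
        own = np.flatnonzero(group_of == grp)
        others = np.flatnonzero(group_of != grp)
        for _ in range(config.n_group_specific_orfs):
            j = special[cursor]
            cursor += 1
            presence[:, j] = False
            presence[own, j] = True
            # a few stray carriers elsewhere, kept below the 10% rule
            for other_grp in groups:
                if other_grp == grp:
                    continue
                cols = np.flatnonzero(group_of == other_grp)
                k = int(np.floor(0.05 * cols.size))
                if k:
                    presence[rng.choice(cols, size=k, replace=False), j] = True
            truth.planted_group_specific_orfs[orf_ids[j]] = grp

    for lin in lineage_names:
        own = np.flatnonzero(lineage_of == lin)
        for _ in range(config.n_lineage_specific_orfs):
            j = special[cursor]
            cursor += 1
            presence[:, j] = False
            presence[own, j] = True
            truth.planted_lineage_specific_orfs[orf_ids[j]] = lin

    for _ in range(config.n_rare_orfs):
        j = special[cursor]
        cursor += 1
        presence[:, j] = False
        presence[rng.integers(0, n_iso), j] = True

    # group-biased variable content among a fifth of the ordinary ORFs;
    # counts realised exactly from clipped frequencies so only planted ORFs
    # can reach the >90%/<10% group-majority rule
    ordinary = np.setdiff1d(np.arange(config.n_orfs), special[:cursor])
    n_var = ordinary.size // 5
    variable = rng.choice(ordinary, size=n_var, replace=False)
    for j in variable:
        presence[:, j] = False
        for grp in groups:
            cols = np.flatnonzero(group_of == grp)
            k = int(round(rng.uniform(0.25, 0.75) * cols.size))
            presence[rng.choice(cols, size=k, replace=False), j] = True

    truth.true_presence = new_presence_matrix(isolates, orf_ids, presence)

    qlens = {o: len(s) for o, s in catalog.items()}
    rows = []
    for i, iso in enumerate(isolates):
        for j, orf in enumerate(orf_ids):
            if presence[i, j]:
                rows.append((orf, iso, True))
            elif rng.random() < 0.3:  # decoy alignment below thresholds
                rows.append((orf, iso, False))
    aln = _alignment_rows(rng, rows, qlens)
    aln.insert(0, "isolate", aln["sseqid"])

    # gene-prediction output: every catalog ORF re-predicted + planted novels
    novel_ids = [f"NOVEL{i + 1:03d}" for i in range(config.n_novel_orfs)]
    novel_seqs = _random_seqs(rng, novel_ids, config.orf_length_range)
    qlens.update({n: len(s) for n, s in novel_seqs.items()})
    pred_rows = [(f"pred_{orf}", orf, True) for orf in orf_ids]
    pred_rows += [(f"pred_{nv}", orf_ids[int(rng.integers(0, config.n_orfs))], False) for nv in novel_ids]
    qlens.update({f"pred_{orf}": qlens[orf] for orf in orf_ids})
    qlens.update({f"pred_{nv}": qlens[nv] for nv in novel_ids})
    predicted_aln = _alignment_rows(rng, pred_rows, qlens)
    predicted_ids = [f"pred_{o}" for o in orf_ids] + [f"pred_{n}" for n in novel_ids]
    truth.planted_novel_orfs = {f"pred_{n}" for n in novel_ids}

    return OrfSimulation(
        catalog=catalog,
        alignments=aln,
        predicted_ids=predicted_ids,
        predicted_alignments=predicted_aln,
        predicted_lengths={q: qlens[q] for q in predicted_ids},
        truth=truth,
    )


def simulate_gene_intervals(config: SimulationConfig, gene_length: int = 300, gap: int = 50) -> pd.DataFrame:
    """Non-overlapping gene intervals tiling the synthetic genome (BED fields).

    The defaults are compact (scaled to the synthetic genome) so that SNP
    sites spread over a number of genes comparable to their real density.
    """
    rows = []
    start = gap
    i = 0
    while start + gene_length < config.genome_length:
        i += 1
        rows.append(("chrI", start, start + gene_length, f"GENE{i:04d}", 0, "+" if i % 2 else "-"))
        start += gene_length + gap
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def simulate_annotations(
    config: SimulationConfig,
    universe: list[str],
    planted_sets: dict[str, set[str]] | None = None,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 40),
) -> dict[str, set[str]]:
    """Term -> gene annotation over ``universe``.

    ``planted_sets`` (name -> genes) become terms padded with random genes,
    so queries drawn from a planted set come out significantly enriched.
    """
    rng = _rng(config, 3)
    universe = list(universe)
    terms: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(*term_size_range))
        size = min(size, len(universe))
        terms[f"TERM{i + 1:04d}"] = set(rng.choice(universe, size=size, replace=False))
    for name, genes in (planted_sets or {}).items():
        pad = set(rng.choice(universe, size=min(10, len(universe)), replace=False))
        terms[f"TERM_{name}"] = (set(genes) & set(universe)) | pad
    return terms


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
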