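"""Filter cascade semantics: boundaries, oracle equivalence, idempotence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scerpop import qc
from scerpop.containers import MISSING

from conftest import make_gm, random_gm


def calls_frame(rows):
    """rows: (isolate, pos, depth, ref, alt, genotype)."""
    return pd.DataFrame(
        [(iso, "chrI", pos, d, r, a, g) for iso, pos, d, r, a, g in rows],
        columns=["isolate", "chrom", "pos", "depth", "ref_reads", "alt_reads", "genotype"],
    )


def random_calls(rng, n=200, isolates=("i1", "i2", "i3")):
    rows = []
    for _ in range(n):
        iso = isolates[rng.integers(len(isolates))]
        pos = int(rng.integers(1, 80))
        depth = int(rng.integers(0, 120))
        ref = int(rng.integers(0, depth + 1))
        alt = int(rng.integers(0, depth - ref + 1))
        g = ["hom_ref", "het", "hom_alt", "missing"][rng.integers(4)]
        rows.append((iso, pos, depth, ref, alt, g))
    df = calls_frame(rows)
    return df.drop_duplicates(subset=["isolate", "chrom", "pos"]).reset_index(drop=True)


class TestConsensusSites:
    def test_intersection_requires_identical_genotype(self):
        a = calls_frame([("i1", 1, 30, 30, 0, "hom_ref"), ("i1", 2, 30, 15, 15, "het")])
        b = calls_frame([("i1", 2, 25, 12, 13, "het"), ("i1", 3, 30, 0, 30, "hom_alt")])
        out = qc.consensus_sites(a, b)
        assert list(out["pos"]) == [2]
        assert list(out["depth"]) == [30]  # caller A's reads

    def test_self_consensus_is_identity_on_called_entries(self):
        rng = np.random.default_rng(0)
        a = random_calls(rng)
        out = qc.consensus_sites(a, a)
        called = a[a["genotype"] != "missing"].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            out.sort_values(["isolate", "pos"], ignore_index=True),
            called.sort_values(["isolate", "pos"], ignore_index=True),
        )

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_calls(rng), random_calls(rng)
            iso = sorted(set(a["isolate"]) | set(b["isolate"]))
            # pad so isolate sets agree
            pad = calls_frame([(i, 999, 20, 20, 0, "hom_ref") for i in iso])
            a = pd.concat([a, pad], ignore_index=True).drop_duplicates(["isolate", "chrom", "pos"])
            b = pd.concat([b, pad], ignore_index=True).drop_duplicates(["isolate", "chrom", "pos"])
            got = set(map(tuple, qc.consensus_sites(a, b)[["isolate", "pos"]].values))
            bmap = {(r.isolate, r.pos): r.genotype for r in b.itertuples()}
            want = {
                (r.isolate, r.pos)
                for r in a.itertuples()
                if r.genotype != "missing" and bmap.get((r.isolate, r.pos)) == r.genotype
            }
            assert got == want

    def test_differing_isolate_sets_rejected(self):
        a = calls_frame([("i1", 1, 30, 30, 0, "hom_ref")])
        b = calls_frame([("i2", 1, 30, 30, 0, "hom_ref")])
        with pytest.raises(ValueError, match="isolate sets differ"):
            qc.consensus_sites(a, b)


class TestDepthFilter:
    MEANS = {"i1": 50.0}

    def entry(self, depth):
        return calls_frame([("i1", 1, depth, depth, 0, "hom_ref")])

    @pytest.mark.parametrize("depth,kept", [
        (14, False),   # below min coverage
        (15, True),    # min coverage boundary is inclusive
        (200, True),   # exactly 4x the isolate mean is kept
        (201, False),  # strictly greater than 4x removed
    ])
    def test_boundaries(self, depth, kept):
        out = qc.depth_filter(self.entry(depth), self.MEANS)
        assert (len(out) == 1) is kept

    def test_unknown_isolate_mean_rejected(self):
        with pytest.raises(ValueError, match="mean depth"):
            qc.depth_filter(self.entry(20), {"other": 50.0})


class TestAlleleSupportFilter:
    @pytest.mark.parametrize("genotype,ref,alt,kept", [
        ("hom_alt", 2, 18, True),    # 90% support
        ("hom_alt", 5, 15, False),   # 75% < 80%
        ("hom_alt", 4, 16, True),    # exactly 80% kept
        ("hom_ref", 16, 4, True),
        ("het", 18, 2, False),       # minor allele 10% < 20%
        ("het", 16, 4, True),        # exactly 20% kept
        ("het", 10, 10, True),
    ])
    def test_boundaries(self, genotype, ref, alt, kept):
        calls = calls_frame([("i1", 1, ref + alt, ref, alt, genotype)])
        assert (len(qc.allele_support_filter(calls)) == 1) is kept

    def test_zero_informative_reads_become_missing(self):
        calls = calls_frame([("i1", 1, 30, 0, 0, "hom_ref")])
        out = qc.allele_support_filter(calls)
        assert list(out["genotype"]) == ["missing"]

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(2)
        calls = random_calls(rng, n=300)
        out = qc.allele_support_filter(calls)
        got = set(map(tuple, out[["isolate", "pos"]].values))
        want = set()
        p = qc.QCParams()
        for r in calls.itertuples():
            tot = r.ref_reads + r.alt_reads
            if r.genotype == "missing":
                want.add((r.isolate, r.pos))
            elif tot == 0:
                want.add((r.isolate, r.pos))  # kept as missing
            elif r.genotype == "hom_ref" and r.ref_reads / tot >= p.hom_support:
                want.add((r.isolate, r.pos))
            elif r.genotype == "hom_alt" and r.alt_reads / tot >= p.hom_support:
                want.add((r.isolate, r.pos))
            elif r.genotype == "het" and min(r.ref_reads, r.alt_reads) / tot >= p.het_support:
                want.add((r.isolate, r.pos))
        assert got == want


class TestMissingnessFilter:
    def test_612_isolate_boundary(self):
        # 7/612 = 1.14% > 1% removed; 6/612 = 0.98% kept; 0 missing kept
        d = np.zeros((3, 612), dtype=np.int8)
        d[0, :7] = MISSING
        d[1, :6] = MISSING
        gm = make_gm(d, isolates=[f"s{i}" for i in range(612)])
        out = qc.missingness_filter(gm)
        assert list(out.sites["pos"]) == [20, 30]

    def test_idempotent(self):
        gm = random_gm(np.random.default_rng(3))
        once = qc.missingness_filter(gm, qc.QCParams(max_missing_frac=0.2))
        twice = qc.missingness_filter(once, qc.QCParams(max_missing_frac=0.2))
        assert np.array_equal(once.dosages, twice.dosages)


class TestMafFilter:
    def test_boundaries_at_100_isolates(self):
        d = np.zeros((3, 100), dtype=np.int8)
        # site 0 monomorphic; site 1 single het (MAF 0.005); site 2 single hom (MAF 0.01)
        d[1, 0] = 1
        d[2, 0] = 2
        gm = make_gm(d, isolates=[f"s{i}" for i in range(100)])
        out = qc.maf_filter(gm)
        assert list(out.sites["pos"]) == [30]

    def test_all_missing_site_removed(self):
        d = np.full((1, 4), MISSING, dtype=np.int8)
        gm = make_gm(d)
        assert qc.maf_filter(gm).n_sites == 0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        gm = random_gm(rng, n_sites=120)
        out = qc.maf_filter(gm)
        kept = set(out.sites["pos"])
        for i in range(gm.n_sites):
            row = gm.dosages[i]
            alleles = [a for dos in row if dos != MISSING for a in ((0, 0), (0, 1), (1, 1))[dos]]
            if not alleles:
                want = False
            else:
                f = sum(alleles) / len(alleles)
                want = min(f, 1 - f) >= 0.01
            assert (gm.sites["pos"][i] in kept) == want


class TestLdPrune:
    def test_duplicated_site_one_copy_removed(self):
        base = np.array([0, 1, 2, 0, 1, 2, 0, 2], dtype=np.int8)
        gm = make_gm(np.vstack([base, base, np.array([0, 0, 2, 2, 0, 2, 0, 2])]))
        out = qc.ld_prune(gm)
        assert out.n_sites == 2
        assert 30 in set(out.sites["pos"])

    def test_perfect_anticorrelation_pruned(self):
        a = np.array([0, 1, 2, 0], dtype=np.int8)
        gm = make_gm(np.vstack([a, 2 - a]))
        out = qc.ld_prune(gm)
        assert out.n_sites == 1

    def test_output_has_no_window_pair_above_threshold(self):
        rng = np.random.default_rng(5)
        # correlated blocks: duplicate sites with occasional noise
        d = rng.integers(0, 3, size=(300, 20)).astype(np.int8)
        for i in range(0, 300, 3):
            for k in (1, 2):
                if i + k < 300:
                    d[i + k] = d[i]
                    flip = rng.random(20) < 0.05
                    d[i + k, flip] = rng.integers(0, 3, size=int(flip.sum()))
        d[rng.random(d.shape) < 0.05] = MISSING
        gm = make_gm(d, isolates=[f"s{i}" for i in range(20)])
        p = qc.QCParams()
        out = qc.ld_prune(gm, p)
        assert out.n_sites < gm.n_sites
        # brute-force all-pairs scan inside every window position
        X = out.dosages.astype(float)
        X[out.dosages == MISSING] = np.nan
        for start in range(0, out.n_sites, p.ld_step):
            win = X[start : start + p.ld_window]
            for i in range(len(win)):
                for j in range(i + 1, len(win)):
                    ok = ~np.isnan(win[i]) & ~np.isnan(win[j])
                    if ok.sum() < 2 or win[i][ok].std() == 0 or win[j][ok].std() == 0:
                        continue
                    r = np.corrcoef(win[i][ok], win[j][ok])[0, 1]
                    assert r * r <= p.r2_max + 1e-12

    def test_prune_output_is_subset_and_idempotent(self):
        gm = random_gm(np.random.default_rng(6), n_sites=150, n_iso=15)
        out = qc.ld_prune(gm)
        assert set(out.sites["pos"]) <= set(gm.sites["pos"])
        again = qc.ld_prune(out)
        assert np.array_equal(again.dosages, out.dosages)


@given(st.integers(0, 2**31 - 1))
def test_cascade_filters_only_remove_sites(seed):
    """Matrix-level filters never edit genotypes, only drop rows."""
    gm = random_gm(np.random.default_rng(seed), n_sites=40, n_iso=8)
    for fn in (qc.missingness_filter, qc.maf_filter, qc.ld_prune):
        out = fn(gm, qc.QCParams(max_missing_frac=0.3))
        kept = gm.sites["pos"].isin(out.sites["pos"]).to_numpy()
        assert np.array_equal(gm.dosages[kept], out.dosages)


def test_qcparams_yaml_round_trip(tmp_path):
    path = tmp_path / "qc.yaml"
    path.write_text("min_coverage: 10\nmaf_min: 0.05\n")
    p = qc.QCParams.from_yaml(path)
    assert p.min_coverage == 10 and p.maf_min == 0.05
    path.write_text("bogus_threshold: 3\n")
    with pytest.raises(ValueError, match="unknown QC parameters"):
        qc.QCParams.from_yaml(path)
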