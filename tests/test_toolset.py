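"""Classification, coverage, inference, counting, reannotation, integration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from probam.annotation import GenomicBlock, TranscriptModel, load_annotation
from probam.fixtures import make_scheme_b, simulate_psms
from probam.mapper import build_probam
from probam.probam_format import ProBAMFile, ProBAMRecord
from probam.psm_io import PSMRecord
from probam.toolset import (
    BipartiteGraph,
    build_bipartite,
    classify_peptides,
    count_tables,
    coverage,
    coverage_saturation,
    coverage_ztest,
    integrate,
    parsimony_infer,
    reannotate,
    rescue_psms,
)

from conftest import build_toy_annotation
from test_annotation import PROTEIN_30, cds_for


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def run20(ref20):
    psms = simulate_psms(ref20.ref.truth, seed=33, n_psms=400, decoy_fraction=0.15)
    return build_probam(psms, ref20.ann, ref20.ref.truth.proteins, psm_fdr=1.0)


@pytest.fixture(scope="module")
def scheme_b(ref20, tmp_path_factory):
    sb = make_scheme_b(ref20.ref)
    path = sb.write(str(tmp_path_factory.mktemp("schemeB")))
    ann_b = load_annotation(path, ref20.fasta, name="schemeB")
    return sb, ann_b


@pytest.fixture(scope="module")
def isoform_world():
    """One gene, two isoforms (B skips the middle exon), four PSMs:

    shared peptide s (2 spectra, both isoforms), A-only peptide a (1),
    B-only junction peptide b (1). Mirrors the worked two-isoform
    counting example."""
    blocks_a = [(100, 130), (200, 230), (300, 330)]
    blocks_b = [
        GenomicBlock("chrT", s, e, "+") for s, e in [(100, 130), (300, 330)]
    ]
    twin = TranscriptModel("TB", "G1", "+", list(blocks_b), list(blocks_b), "PB")
    ann = build_toy_annotation(
        cds_for(PROTEIN_30),
        blocks_a,
        transcript_id="TA",
        protein_id="PA",
        extra_transcripts=[twin],
    )
    prot_a = PROTEIN_30
    prot_b = PROTEIN_30[:10] + PROTEIN_30[20:]
    s, a, b = prot_a[1:7], prot_a[11:17], prot_b[8:14]
    assert s in prot_a and s in prot_b and a not in prot_b and b not in prot_a
    proteins = {"PA": prot_a, "PB": prot_b}
    psms = [
        PSMRecord("q.s1", s, score=9.0, charge=2, protein_hits=["PA", "PB"]),
        PSMRecord("q.s2", s, score=8.0, charge=2, protein_hits=["PA", "PB"]),
        PSMRecord("q.a1", a, score=7.0, charge=2, protein_hits=["PA"]),
        PSMRecord("q.b1", b, score=6.0, charge=2, protein_hits=["PB"]),
    ]
    file = build_probam(psms, ann, proteins)
    return ann, file, {"s": s, "a": a, "b": b}


# ---------------------------------------------------------------------------
# peptide classification
# ---------------------------------------------------------------------------

class TestClassifyPeptides:
    def _single_record_file(self, cigar, peptide, flag=0, pos=10):
        m_total = 3 * len(peptide)
        rec = ProBAMRecord(
            qname="q1",
            flag=flag,
            rname="chr1",
            pos=pos,
            cigar=cigar,
            seq="A" * m_total,
            peptide=peptide,
            score=1.0,
            charge=2,
            nh=1,
        )
        return ProBAMFile(sq={"chr1": 100000}, records=[rec])

    def test_junction_peptide_spanning_two_exons(self):
        file = self._single_record_file("12M300N12M", "PEPTIDEK")
        (row,) = classify_peptides(file)
        assert (row.n_locations, row.junction, row.exons_spanned) == (1, True, 2)

    def test_multi_location_peptide(self):
        file = self._single_record_file("18M", "PEPTIK")
        file.records.append(
            ProBAMRecord(
                qname="q1",
                flag=256,
                rname="chr1",
                pos=5000,
                cigar="18M",
                seq="A" * 18,
                peptide="PEPTIK",
                score=1.0,
                charge=2,
                nh=2,
            )
        )
        (row,) = classify_peptides(file)
        assert row.n_locations == 2

    def test_three_exon_spanning_peptide(self, isoform_world):
        ann, _, _ = isoform_world
        pep = PROTEIN_30[7:22]  # crosses both introns of isoform A
        file = build_probam(
            [PSMRecord("q.3x", pep, score=1.0, charge=2, protein_hits=["PA"])],
            ann,
            {"PA": PROTEIN_30},
        )
        (row,) = classify_peptides(file)
        assert row.exons_spanned == 3 and row.junction

    def test_decoys_excluded(self, run20):
        rows = classify_peptides(run20)
        decoy_peps = {r.peptide for r in run20.records if r.decoy}
        target_peps = {r.peptide for r in run20.records if not r.decoy and r.is_mapped}
        assert {row.peptide for row in rows} == target_peps
        # decoy-only sequences never classified
        assert not ({row.peptide for row in rows} & (decoy_peps - target_peps))

    def test_partition_of_target_peptides(self, run20):
        rows = classify_peptides(run20)
        unique = [r for r in rows if r.n_locations == 1]
        multi = [r for r in rows if r.n_locations > 1]
        assert len(unique) + len(multi) == len(rows)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

class TestCoverage:
    @pytest.fixture()
    def toy(self):
        return build_toy_annotation(cds_for(PROTEIN_30), [(100, 130), (200, 260)])

    def _record(self, pos, cigar, n_aa):
        return ProBAMRecord(
            qname=f"q{pos}",
            flag=0,
            rname="chrT",
            pos=pos,
            cigar=cigar,
            seq="A" * (3 * n_aa),
            peptide="K" * n_aa,
            score=1.0,
            charge=2,
            nh=1,
        )

    def test_single_peptide_fraction(self, toy):
        file = ProBAMFile(sq={"chrT": 1000}, records=[self._record(101, "30M", 10)])
        assert coverage(file, toy, "gene") == {"G1": pytest.approx(1 / 3)}

    def test_no_records_zero_everywhere(self, toy):
        file = ProBAMFile(sq={"chrT": 1000})
        assert coverage(file, toy, "gene") == {"G1": 0.0}
        assert coverage(file, toy, "genome") == 0.0

    def test_complete_tiling_reaches_one(self, toy):
        file = ProBAMFile(
            sq={"chrT": 1000},
            records=[self._record(101, "30M", 10), self._record(201, "60M", 20)],
        )
        assert coverage(file, toy, "gene")["G1"] == 1.0

    def test_monotone_under_record_addition(self, toy):
        small = ProBAMFile(sq={"chrT": 1000}, records=[self._record(101, "30M", 10)])
        big = ProBAMFile(sq={"chrT": 1000}, records=small.records + [self._record(201, "30M", 10)])
        assert coverage(big, toy, "genome") >= coverage(small, toy, "genome")

    def test_chromosome_fractions_average_to_genome(self, run20, ref20):
        by_chrom = coverage(run20, ref20.ann, "chromosome")
        genome = coverage(run20, ref20.ann, "genome")
        from probam.toolset import _cds_union_by_chrom
        from probam import intervals
        sizes = {
            c: intervals.total_length(iv)
            for c, iv in _cds_union_by_chrom(ref20.ann).items()
        }
        weighted = sum(by_chrom[c] * sizes[c] for c in sizes) / sum(sizes.values())
        assert weighted == pytest.approx(genome)

    def test_unknown_level(self, toy):
        with pytest.raises(ValueError, match="unknown level"):
            coverage(ProBAMFile(sq={}), toy, "exome")


class TestCoverageZtest:
    def test_null_center(self):
        z, p = coverage_ztest(50, 100, 0.5)
        assert z == 0.0 and p == 0.5

    def test_two_sigma_below(self):
        z, p = coverage_ztest(40, 100, 0.5)
        assert z == pytest.approx(-2.0)
        assert p == pytest.approx(stats.norm.cdf(-2.0))

    def test_above_average_gives_large_p(self):
        _, p = coverage_ztest(70, 100, 0.5)
        assert p > 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            coverage_ztest(1, 0, 0.5)
        with pytest.raises(ValueError):
            coverage_ztest(1, 10, 1.0)


class TestCoverageSaturation:
    @pytest.fixture()
    def nested_samples(self, ref20):
        psms = simulate_psms(ref20.ref.truth, seed=44, n_psms=120, decoy_fraction=0.0)
        f_small = build_probam(psms[:20], ref20.ann, ref20.ref.truth.proteins)
        f_mid = build_probam(psms[:60], ref20.ann, ref20.ref.truth.proteins)
        f_full = build_probam(psms, ref20.ann, ref20.ref.truth.proteins)
        return [f_small, f_mid, f_full]

    def test_full_subset_equals_union_coverage(self, nested_samples, ref20):
        table = coverage_saturation(nested_samples, ref20.ann, draws_per_size=4, seed=1)
        from probam.probam_format import merge_probam
        full = coverage(merge_probam(nested_samples), ref20.ann, "genome")
        at_n = table[table.sample_size == 3].coverage
        assert np.allclose(at_n, full)

    def test_identical_samples_flat_curve(self, nested_samples, ref20):
        same = [nested_samples[2]] * 3
        table = coverage_saturation(same, ref20.ann, draws_per_size=3, seed=2)
        assert table.coverage.nunique() == 1

    def test_mean_curve_non_decreasing(self, nested_samples, ref20):
        table = coverage_saturation(nested_samples, ref20.ann, draws_per_size=6, seed=3)
        means = table.groupby("sample_size").coverage.mean()
        assert (means.diff().dropna() >= -1e-12).all()

    def test_reproducible_under_seed(self, nested_samples, ref20):
        t1 = coverage_saturation(nested_samples, ref20.ann, draws_per_size=3, seed=5)
        t2 = coverage_saturation(nested_samples, ref20.ann, draws_per_size=3, seed=5)
        assert t1.equals(t2)

    def test_bad_draws(self, nested_samples, ref20):
        with pytest.raises(ValueError):
            coverage_saturation(nested_samples, ref20.ann, draws_per_size=0, seed=1)


# ---------------------------------------------------------------------------
# bipartite graph + parsimony
# ---------------------------------------------------------------------------

class TestBuildBipartite:
    def test_isoform_discrimination(self, isoform_world):
        ann, file, peps = isoform_world
        prot = build_bipartite(file, ann, "protein")
        gene = build_bipartite(file, ann, "gene")
        assert prot.peptide_features[(peps["s"], False)] == {"PA", "PB"}
        assert prot.peptide_features[(peps["a"], False)] == {"PA"}
        assert prot.peptide_features[(peps["b"], False)] == {"PB"}
        assert all(
            gene.peptide_features[(p, False)] == {"G1"} for p in peps.values()
        )

    def test_peptide_outside_any_cds_is_isolated(self, isoform_world):
        ann, file, _ = isoform_world
        stray = ProBAMRecord(
            qname="q.stray",
            flag=0,
            rname="chrT",
            pos=601,
            cigar="18M",
            seq="A" * 18,
            peptide="KKKKKK",
            score=1.0,
            charge=2,
            nh=1,
        )
        graph = build_bipartite(
            ProBAMFile(sq=file.sq, records=file.records + [stray]), ann, "gene"
        )
        assert graph.peptide_features[("KKKKKK", False)] == set()

    def test_decoys_connect_to_decoy_twins(self, run20, ref20):
        graph = build_bipartite(run20, ref20.ann, "gene")
        for (pep, is_decoy), feats in graph.peptide_features.items():
            if is_decoy:
                assert all(f.startswith("rev_") for f in feats)
                assert feats <= graph.decoy_features

    def test_unknown_level(self, isoform_world):
        ann, file, _ = isoform_world
        with pytest.raises(ValueError, match="level"):
            build_bipartite(file, ann, "exon")


def graph_from_sets(sets, decoys=()):
    g = BipartiteGraph(level="protein")
    for feature, peps in sets.items():
        for p in peps:
            g.add_edge((p, feature in decoys), feature, feature in decoys)
    return g


def random_bipartite(seed):
    """Random isoform-cluster graph: peptides connect to a nonempty subset
    of one gene's (≤2) isoforms — the synthetic gene model's sharing
    structure, under which greedy set cover is provably optimal."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, 9))
    isoforms = [2 if rng.random() < 0.5 else 1 for _ in range(n_genes)]
    while sum(isoforms) > 12:
        isoforms[int(rng.integers(0, n_genes))] = 1
    feats = [[f"G{g}I{i}" for i in range(k)] for g, k in enumerate(isoforms)]
    n_pep = int(rng.integers(sum(isoforms), 26))
    g = BipartiteGraph(level="protein")
    for p in range(n_pep):
        pep = (f"PEP{p:02d}", False)
        cluster = feats[int(rng.integers(0, n_genes))]
        mask = rng.random(len(cluster)) < 0.6
        if not mask.any():
            mask[int(rng.integers(0, len(cluster)))] = True
        for f, m in zip(cluster, mask):
            if m:
                g.add_edge(pep, f, False)
    return g


def exhaustive_min_cover_size(g):
    """Brute-force minimum set cover over collapsed feature groups."""
    sets = {}
    for f, peps in g.feature_peptides.items():
        if peps:
            sets.setdefault(frozenset(peps), f)
    universe = set().union(*sets.keys())
    groups = list(sets.keys())
    for k in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, k):
            if set().union(*combo) == universe:
                return k
    return len(groups)


class TestParsimonyInfer:
    def test_subsumption_and_min_two_filter(self):
        g = graph_from_sets({"A": ["p1", "p2", "p3"], "B": ["p2", "p3"], "C": ["p4"]})
        result = parsimony_infer(g)
        assert result.subsumed == ["B"]
        assert [grp.members for grp in result.groups] == [("A",)]
        assert [grp.members for grp in result.single_hit_groups] == [("C",)]
        assert result.cover_size == 2

    def test_indistinguishable_features_collapse(self):
        g = graph_from_sets({"A": ["p1", "p2"], "B": ["p1", "p2"]})
        result = parsimony_infer(g)
        assert [grp.members for grp in result.groups] == [("A", "B")]
        assert result.groups[0].representative == "A"

    def test_all_decoy_groups_cap_fdr_at_one(self):
        g = graph_from_sets(
            {"rev_X": ["d1", "d2"], "rev_Y": ["d3", "d4"]}, decoys={"rev_X", "rev_Y"}
        )
        result = parsimony_infer(g)
        assert result.group_fdr == 1.0
        assert all(grp.is_decoy for grp in result.groups)

    def test_mixed_group_counts_as_target(self):
        g = BipartiteGraph(level="protein")
        for p in ("p1", "p2"):
            g.add_edge((p, False), "A", False)
            g.add_edge((p, False), "rev_B", True)
        result = parsimony_infer(g)
        assert len(result.groups) == 1 and not result.groups[0].is_decoy

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_matches_exhaustive_minimum(self, seed):
        g = random_bipartite(seed)
        assert parsimony_infer(g).cover_size == exhaustive_min_cover_size(g)

    def test_every_edge_peptide_covered_before_filter(self):
        g = random_bipartite(7)
        result = parsimony_infer(g)
        covered = set()
        for grp in result.groups + result.single_hit_groups:
            covered |= grp.peptides
        with_edges = {p for p, fs in g.peptide_features.items() if fs}
        assert covered == with_edges


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

class TestCountTables:
    def test_two_isoform_worked_example(self, isoform_world):
        ann, file, _ = isoform_world
        prot = count_tables(file, build_bipartite(file, ann, "protein"))
        gene = count_tables(file, build_bipartite(file, ann, "gene"))
        assert prot.loc["PA"].tolist() == [3, 1, 2, 1]
        assert prot.loc["PB"].tolist() == [3, 1, 2, 1]
        assert gene.loc["G1"].tolist() == [4, 4, 3, 3]

    def test_overcounting_at_protein_level_only(self, isoform_world):
        ann, file, peps = isoform_world
        prot = count_tables(file, build_bipartite(file, ann, "protein"))
        gene = count_tables(file, build_bipartite(file, ann, "gene"))
        n_distinct = len(peps)
        assert gene.overall_peptide.sum() == n_distinct
        assert prot.overall_peptide.sum() > n_distinct

    def test_specific_bounded_by_overall(self, run20, ref20):
        table = count_tables(run20, build_bipartite(run20, ref20.ann, "gene"))
        assert (table.specific_spectral <= table.overall_spectral).all()
        assert (table.specific_peptide <= table.overall_peptide).all()

    def test_feature_with_only_specific_peptides(self, isoform_world):
        ann, file, _ = isoform_world
        gene = count_tables(file, build_bipartite(file, ann, "gene"))
        assert (gene.loc["G1", "overall_spectral"] == gene.loc["G1", "specific_spectral"])


# ---------------------------------------------------------------------------
# reannotation
# ---------------------------------------------------------------------------

class TestReannotate:
    def test_identity_scheme_retains_everything(self, run20, ref20):
        result = reannotate(run20, ref20.ann)
        assert result.retained_fraction == 1.0
        assert all(not v for v in result.dropped_by_step.values())

    def test_scheme_b_drops_exactly_the_predicted_records(self, run20, scheme_b):
        sb, ann_b = scheme_b
        result = reannotate(run20, ann_b)
        key = lambda r: (r.qname, r.rname, r.pos, r.flag)
        for step in (1, 2, 3):
            expected = {
                key(r)
                for r in run20.mapped_records()
                if sb.expected_drop_step(r) == step
            }
            assert {key(r) for r in result.dropped_by_step[step]} == expected

    def test_never_increases_record_count(self, run20, scheme_b):
        _, ann_b = scheme_b
        result = reannotate(run20, ann_b)
        n_mapped = len(run20.mapped_records())
        n_dropped = sum(len(v) for v in result.dropped_by_step.values())
        assert len(result.file.records) + n_dropped == n_mapped
        assert result.retained_fraction == pytest.approx(
            len(result.file.records) / n_mapped
        )

    def test_genome_build_mismatch_fatal(self, run20, ref20):
        bad = ProBAMFile(sq=dict(run20.sq), records=run20.records)
        first = next(iter(bad.sq))
        bad.sq[first] += 1
        with pytest.raises(ValueError, match="length mismatch"):
            reannotate(bad, ref20.ann)


# ---------------------------------------------------------------------------
# integration + rescue
# ---------------------------------------------------------------------------

class TestIntegrate:
    def test_self_integration_doubles_spectra_not_peptides(self, run20, ref20):
        once = integrate([run20], ref20.ann, psm_fdr=1.0)
        twice = integrate([run20, run20], ref20.ann, psm_fdr=1.0)
        assert [g.members for g in once.gene_inference.groups] == [
            g.members for g in twice.gene_inference.groups
        ]
        g1 = once.combined_counts["gene"]
        g2 = twice.combined_counts["gene"]
        assert (g2.overall_spectral == 2 * g1.overall_spectral).all()
        assert (g2.overall_peptide == g1.overall_peptide).all()

    def test_stricter_filter_keeps_fewer_spectra(self, run20, ref20):
        loose = integrate([run20], ref20.ann, psm_fdr=0.05)
        strict = integrate([run20], ref20.ann, psm_fdr=0.005)
        assert strict.fdr_report["n_spectra"] <= loose.fdr_report["n_spectra"]
        assert strict.fdr_report["gene_group_fdr"] <= loose.fdr_report["gene_group_fdr"]


@pytest.fixture(scope="module")
def rescue_setup(run20, ref20):
    strict_fdr, relaxed_fdr = 0.001, 0.05
    strict_file = integrate([run20], ref20.ann, psm_fdr=strict_fdr)
    return run20, strict_file.gene_inference, strict_fdr, relaxed_fdr


class TestRescuePsms:
    def test_relaxed_equal_strict_is_identity(self, rescue_setup, ref20):
        merged, confident, strict_fdr, _ = rescue_setup
        from probam.toolset import refilter_by_psm_fdr
        rescued = rescue_psms(merged, confident, strict_fdr, strict_fdr, ref20.ann)
        baseline = refilter_by_psm_fdr(merged, strict_fdr)
        assert {r.qname for r in rescued.records} == {r.qname for r in baseline.records}

    def test_rescued_only_on_confident_features(self, rescue_setup, ref20):
        merged, confident, strict_fdr, relaxed_fdr = rescue_setup
        from probam.toolset import _per_spectrum_qvalues, refilter_by_psm_fdr
        rescued = rescue_psms(merged, confident, strict_fdr, relaxed_fdr, ref20.ann)
        strict_qnames = {
            r.qname for r in refilter_by_psm_fdr(merged, strict_fdr).records
        }
        added = {r.qname for r in rescued.records} - strict_qnames
        assert added  # the relaxed band is not empty on this fixture
        qvalues = _per_spectrum_qvalues(merged)
        graph = build_bipartite(merged, ref20.ann, "gene")
        confident_features = confident.target_features()
        for rec in rescued.records:
            if rec.qname not in added:
                continue
            assert strict_fdr < qvalues[rec.qname] <= relaxed_fdr
            feats = graph.peptide_features[(rec.peptide, bool(rec.decoy))]
            assert feats and feats <= confident_features

    def test_invalid_thresholds(self, rescue_setup, ref20):
        merged, confident, strict_fdr, _ = rescue_setup
        with pytest.raises(ValueError, match="relaxed_fdr"):
            rescue_psms(merged, confident, strict_fdr, strict_fdr / 2, ref20.ann)
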