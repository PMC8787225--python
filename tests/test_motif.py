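"""PWM scanning with exact p-values, promoters, peak profiles, nomination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfact.diffexp import DEGSets
from tfact.io import GeneModel
from tfact.motif import (
    Pwm,
    extract_promoters,
    nominate_targets,
    peak_tss_profile,
    pearson,
    reverse_complement,
    scan_pwm,
)

BASES = "ACGT"


def _random_pwm(rng, width, background=None):
    counts = rng.uniform(0.1, 20.0, (4, width))
    return Pwm(counts, background=background)


def _enumerate_tail(pwm):
    """Oracle: exact tail over all 4^w k-mers using the integer score grid."""
    w = pwm.width
    scores = {}
    for kmer in itertools.product(range(4), repeat=w):
        s = int(sum(pwm.int_scores[b, j] for j, b in enumerate(kmer)))
        prob = float(np.prod([pwm.background[b] for b in kmer]))
        scores[kmer] = (s, prob)
    out = {}
    for kmer, (s, _) in scores.items():
        out[kmer] = sum(p for s2, p in scores.values() if s2 >= s)
    return scores, out


class TestPwmExactP:
    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_dp_equals_exhaustive_enumeration(self, width):
        """DP tail equals the k-mer enumeration oracle at every k-mer."""
        rng = np.random.default_rng(width)
        bg = rng.dirichlet([5, 5, 5, 5])
        pwm = _random_pwm(rng, width, background=bg)
        scores, tails = _enumerate_tail(pwm)
        for kmer, (s, _) in scores.items():
            assert float(pwm.pvalue_int(s)) == pytest.approx(tails[kmer], abs=1e-12)

    def test_discretization_error_bound(self):
        """Grid rounding moves a window score by at most width/2 grid steps."""
        rng = np.random.default_rng(3)
        pwm = _random_pwm(rng, 5)
        for kmer in itertools.product(range(4), repeat=5):
            exact = sum(pwm.log_odds[b, j] for j, b in enumerate(kmer))
            grid = sum(pwm.int_scores[b, j] for j, b in enumerate(kmer))
            assert abs(exact - grid * pwm.granularity) <= 5 * pwm.granularity / 2

    def test_pvalue_monotone_in_score(self):
        pwm = _random_pwm(np.random.default_rng(0), 6)
        sf, mn = pwm._tail
        assert (np.diff(sf) <= 1e-15).all()
        assert sf[0] == pytest.approx(1.0)

    def test_consensus_probability(self):
        """A near-consensus width-8 matrix: best hit has p = 4^-8 < 1e-4."""
        pwm = Pwm.from_consensus("AGATAAGA", nsites=1000)  # not rc-palindromic
        hits = scan_pwm("TTTTAGATAAGATT", pwm)
        assert len(hits) == 1
        assert hits[0].p_value == pytest.approx(0.25**8)
        assert hits[0].p_value < 1e-4

    def test_uniform_pwm_never_hits(self):
        pwm = Pwm(np.full((4, 6), 0.25), pseudocount=0.0)
        assert scan_pwm("ACGTACGTACGTACGT", pwm, p_threshold=0.999) == []

    def test_short_sequence_empty(self):
        pwm = Pwm.from_consensus("ACGTAC")
        assert scan_pwm("ACG", pwm) == []

    def test_window_with_n_skipped(self):
        pwm = Pwm.from_consensus("ACGTACGT", nsites=1000)
        assert scan_pwm("ACGTNCGT", pwm) == []

    def test_reverse_complement_mirroring(self):
        """Scanning the reverse complement reproduces hits at mirrored offsets."""
        rng = np.random.default_rng(11)
        pwm = Pwm.from_consensus("AGATAAGA", nsites=1000)
        seq = "".join(rng.choice(list(BASES), 60)) + "AGATAAGA" + "".join(
            rng.choice(list(BASES), 32)
        )
        fwd = scan_pwm(seq, pwm)
        rev = scan_pwm(reverse_complement(seq), pwm)
        assert len(fwd) == len(rev) > 0
        n, w = len(seq), pwm.width
        mirrored = sorted((n - h.offset - w, {"+": "-", "-": "+"}[h.strand]) for h in rev)
        assert sorted((h.offset, h.strand) for h in fwd) == mirrored

    def test_meme_round_trip(self, tmp_path):
        pwm = Pwm.from_consensus("GATAAG", nsites=500)
        path = tmp_path / "m.meme"
        pwm.to_meme(path, nsites=500)
        back = Pwm.from_meme(path)
        # 6-decimal truncation plus a second pseudocount bound the round-trip
        np.testing.assert_allclose(pwm.probs, back.probs, atol=2e-3)
        assert back.consensus == pwm.consensus


class TestPromoters:
    def _genome(self):
        rng = np.random.default_rng(42)
        return {"c1": "".join(rng.choice(list(BASES), 2000))}

    def test_plus_strand_window_arithmetic(self):
        genome = self._genome()
        model = GeneModel("g", "c1", 1000, 1500, "+", 500)
        prom = extract_promoters([model], genome, half_window=100)
        assert prom["g"] == genome["c1"][900:1100]

    def test_minus_strand_reverse_complement(self):
        genome = self._genome()
        model = GeneModel("g", "c1", 100, 600, "-", 500)
        assert model.tss == 599
        prom = extract_promoters([model], genome, half_window=100)
        assert prom["g"] == reverse_complement(genome["c1"][499:699])

    def test_truncated_and_missing_dropped(self):
        genome = self._genome()
        edge = GeneModel("edge", "c1", 50, 500, "+", 450)
        lost = GeneModel("lost", "cX", 500, 900, "+", 400)
        prom = extract_promoters([edge, lost], genome, half_window=100)
        assert prom == {}

    def test_planted_kmer_at_predicted_position(self):
        genome = self._genome()
        seq = genome["c1"]
        genome["c1"] = seq[:1040] + "TTAAGGCC" + seq[1048:]
        model = GeneModel("g", "c1", 1000, 1400, "+", 400)
        prom = extract_promoters([model], genome, half_window=100)
        assert prom["g"][140:148] == "TTAAGGCC"


class TestPeakProfile:
    def _models(self):
        return [
            GeneModel("a", "c1", 1000, 1400, "+", 400),
            GeneModel("b", "c1", 5000, 5600, "-", 600),
        ]

    def test_midpoint_on_tss(self):
        peaks = pd.DataFrame({"chrom": ["c1"], "start": [990], "end": [1010]})
        prof = peak_tss_profile(peaks, self._models())
        assert prof.distances.tolist() == [0]
        assert prof.n_within_near == prof.n_within_core == 1

    def test_minus_strand_tss_convention(self):
        # TSS of gene b is end-1 = 5599
        peaks = pd.DataFrame({"chrom": ["c1"], "start": [5589], "end": [5609]})
        prof = peak_tss_profile(peaks, self._models())
        assert prof.distances.tolist() == [0]

    def test_chromosome_without_genes_skipped(self):
        peaks = pd.DataFrame({"chrom": ["cX"], "start": [0], "end": [10]})
        prof = peak_tss_profile(peaks, self._models())
        assert prof.n_skipped == 1 and len(prof.distances) == 0

    def test_translation_invariance(self, small_world):
        w = small_world
        prof = peak_tss_profile(w["peaks"], w["models"])
        shift = 12_345
        shifted_models = [
            GeneModel(m.gene_id, m.chrom, m.start + shift, m.end + shift, m.strand,
                      m.exonic_length_bp, m.biotype)
            for m in w["models"]
        ]
        shifted_peaks = w["peaks"].assign(
            start=w["peaks"]["start"] + shift, end=w["peaks"]["end"] + shift
        )
        prof2 = peak_tss_profile(shifted_peaks, shifted_models)
        assert prof.fraction_core == prof2.fraction_core

    def test_planted_fraction_recovered(self, small_world):
        """Measured near-TSS core fraction matches the generator's within 0.03."""
        w = small_world
        prof = peak_tss_profile(
            w["peaks"], [m for m in w["models"] if m.biotype == "protein_coding"]
        )
        assert prof.fraction_core == pytest.approx(
            w["truth"].planted_fraction_core, abs=0.03
        )


class TestPearson:
    def test_identity(self):
        r, _ = pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_reversal(self):
        r, _ = pearson([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestNomination:
    def _fpkm(self, genes, n_samples, rng):
        return pd.DataFrame(
            rng.uniform(0.5, 50, (len(genes), n_samples)),
            index=genes,
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_motif_gene_not_deg_excluded(self, rng):
        fpkm = self._fpkm(["tf", "m1", "m2"], 10, rng)
        degs = DEGSets(up={"m1"}, down=set())
        cands = nominate_targets({"m1", "m2"}, degs, fpkm, "tf", fpkm.columns)
        assert [c.gene_id for c in cands] == ["m1"]
        assert cands[0].deg_direction == "up"

    def test_set_algebra_invariant(self, rng):
        genes = [f"g{i}" for i in range(30)] + ["tf"]
        fpkm = self._fpkm(genes, 20, rng)
        motif_genes = {f"g{i}" for i in range(0, 30, 2)}
        degs = DEGSets(up={f"g{i}" for i in range(10)}, down={f"g{i}" for i in range(20, 26)})
        cands = nominate_targets(motif_genes, degs, fpkm, "tf", fpkm.columns)
        named = {c.gene_id for c in cands}
        assert named <= motif_genes
        assert named <= (degs.up | degs.down)
        assert named == motif_genes & (degs.up | degs.down)

    def test_coregulated_target_positive_correlation(self, rng):
        """A target co-regulated with the TF has r > 0, p < 0.05 at n large."""
        n = 200
        tf = rng.gamma(2, 5, n)
        target = tf * rng.lognormal(0, 0.4, n)
        fpkm = pd.DataFrame(
            [tf, target], index=["tf", "t1"], columns=[f"s{i}" for i in range(n)]
        )
        degs = DEGSets(up={"t1"}, down=set())
        (cand,) = nominate_targets({"t1"}, degs, fpkm, "tf", fpkm.columns)
        assert cand.pearson_r > 0 and cand.pearson_p < 0.05
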