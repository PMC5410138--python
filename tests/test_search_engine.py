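"""Scoring correctness against the exhaustive oracle, calibration, E-values."""

import math

import numpy as np
import pytest

from _oracles import oracle_forward, oracle_viterbi
from conftest import random_small_model
from hmmscreen import profile_build as pb
from hmmscreen import search_engine as se
from hmmscreen import synthetic_data as sd
from hmmscreen.profile_build import AA_ORDER, GumbelParams
from hmmscreen.search_engine import (
    CalibrationError,
    SearchConfig,
    alignment_bounds,
    calibrate,
    evalue_of,
    forward_score,
    forward_scores,
    search,
    viterbi_align,
    viterbi_scores,
)


def random_peptide(rng, L, with_x=False):
    alphabet = list(AA_ORDER + ("X" if with_x else ""))
    return "".join(rng.choice(alphabet, size=L))


class TestScoringOracle:
    def test_forward_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(100)
        for _ in range(40):
            model = random_small_model(rng, int(rng.integers(1, 4)))
            pep = random_peptide(rng, int(rng.integers(1, 5)), with_x=True)
            assert forward_score(model, pep) == pytest.approx(
                oracle_forward(model, pep), abs=1e-9
            )
            v, _ = viterbi_align(model, pep)
            assert v == pytest.approx(oracle_viterbi(model, pep), abs=1e-9)

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(101)
        model = random_small_model(rng, 6)
        peps = [random_peptide(rng, int(rng.integers(3, 40))) for _ in range(30)]
        f = forward_scores(model, peps)
        v = viterbi_scores(model, peps)
        assert (f >= v - 1e-9).all()

    def test_all_x_peptide_scores_at_most_zero(self):
        rng = np.random.default_rng(102)
        for M in (1, 3, 8):
            model = random_small_model(rng, M)
            for L in (1, 5, 40):
                assert forward_score(model, "X" * L) <= 1e-9

    def test_empty_peptide_rejected(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            forward_score(toy_model, "")
        with pytest.raises(ValueError, match="empty"):
            viterbi_align(toy_model, "")


class TestViterbiPath:
    def test_path_rescoring_reproduces_score(self):
        rng = np.random.default_rng(103)
        for _ in range(10):
            model = random_small_model(rng, int(rng.integers(2, 6)))
            pep = random_peptide(rng, int(rng.integers(4, 20)))
            score, path = viterbi_align(model, pep)
            # re-sum the path's own log terms
            sm = se._ScoringModel(model)
            res = [pb.AA_INDEX.get(a, 20) for a in pep]
            logp = -math.log(model.M) - math.log(len(pep))
            prev = None
            for state, k, i in path:
                if state == "M":
                    if prev is not None:
                        ps, pk = prev
                        logp += {
                            "M": sm.a_MM[pk - 1],
                            "I": sm.a_IM[pk - 1],
                            "D": sm.a_DM[pk - 1],
                        }[ps]
                    logp += sm.lmatch[k - 1, res[i - 1]]
                elif state == "I":
                    logp += sm.a_MI[k - 1] if prev[0] == "M" else sm.a_II[k - 1]
                    logp += sm.lins[k, res[i - 1]]
                else:
                    logp += sm.a_MD[k - 2] if prev[0] == "M" else sm.a_DD[k - 2]
                prev = (state, k)
            logp += sm.ltexit[path[-1][1] - 1]
            assert logp / se.LN2 == pytest.approx(score, abs=1e-9)

    def test_path_is_admissible_and_deterministic(self, toy_model):
        pep = "ACDEFGHIKLMN"
        s1, p1 = viterbi_align(toy_model, pep)
        s2, p2 = viterbi_align(toy_model, pep)
        assert s1 == s2 and p1 == p2
        assert p1[0][0] == "M" and p1[-1][0] == "M"
        for (s_a, k_a, i_a), (s_b, k_b, i_b) in zip(p1, p1[1:]):
            assert k_b - k_a in (0, 1)
            assert i_b - i_a in (0, 1)

    def test_alignment_bounds_cover_emitted_residues(self, toy_model):
        _, path = viterbi_align(toy_model, "ACDEFGHIKL")
        a, b = alignment_bounds(path)
        assert 1 <= a <= b <= 10


class TestCalibration:
    def test_reproducible_given_seed(self, toy_model):
        g1 = calibrate(toy_model, n_random=300, seed=7)
        g2 = calibrate(toy_model, n_random=300, seed=7)
        assert (g1.mu, g1.lam) == (g2.mu, g2.lam)

    def test_gumbel_ml_moment_check(self):
        # fitted mean mu + gamma/lambda matches the empirical mean within 3 SE
        model = sd.random_profile(8, seed=3)
        rng = np.random.default_rng(8)
        lengths = np.maximum(5, np.round(rng.gamma(3.0, 80 / 3.0, size=600))).astype(int)
        peps = ["".join(rng.choice(list(AA_ORDER), size=L, p=model.background)) for L in lengths]
        scores = forward_scores(model, peps)
        g = calibrate(model, n_random=600, length_dist=(80, 3.0), seed=8, fit="gumbel_ml")
        gamma = 0.5772156649
        fitted_mean = g.mu + gamma / g.lam
        se_mean = scores.std(ddof=1) / math.sqrt(len(scores))
        assert abs(fitted_mean - scores.mean()) <= 3 * se_mean

    def test_mu_standard_error_shrinks_with_n(self):
        model = sd.random_profile(6, seed=4)
        mus = {n: [] for n in (200, 800)}
        for n in mus:
            for s in range(8):
                g = calibrate(model, n_random=n, seed=50 + s, fit="gumbel_ml")
                mus[n].append(g.mu)
        sd_small = np.std(mus[200], ddof=1)
        sd_large = np.std(mus[800], ddof=1)
        # 4x the sample -> about half the SE; allow generous slack
        assert sd_large < sd_small

    def test_too_few_random_sequences_rejected(self, toy_model):
        with pytest.raises(ValueError, match=">= 100"):
            calibrate(toy_model, n_random=50, seed=1)


class TestEvalues:
    def test_closed_form_at_mu(self):
        g = GumbelParams(mu=5.0, lam=0.7, n_calibration=100, seed=0)
        assert evalue_of(5.0, g, 1) == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_monotone_decreasing_and_limit(self):
        g = GumbelParams(mu=0.0, lam=0.7, n_calibration=100, seed=0)
        evs = [evalue_of(s, g, 100) for s in np.linspace(-5, 2000, 200)]
        assert all(a >= b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-250

    def test_linear_in_z(self):
        g = GumbelParams(mu=0.0, lam=0.7, n_calibration=100, seed=0)
        assert evalue_of(3.0, g, 500) == pytest.approx(500 * evalue_of(3.0, g, 1))

    def test_uncalibrated_model_raises(self, toy_model):
        with pytest.raises(CalibrationError):
            evalue_of(1.0, None, 10)


class TestSearch:
    @pytest.fixture(scope="class")
    def calibrated(self):
        model = sd.random_profile(12, seed=6)
        calibrate(model, n_random=1000, seed=11)
        return model

    def test_threshold_inclusive(self, calibrated):
        # construct hits straddling the cutoff by inverting the E-value map
        g = calibrated.calibration

        def score_for(ev, Z):
            return g.mu - math.log(-math.log1p(-ev / Z)) / g.lam

        homolog = "".join(
            AA_ORDER[i] for i in calibrated.match_emit.argmax(axis=1)
        )
        hits = search(calibrated, [homolog], SearchConfig(evalue_cutoff=1e-5, Z=1))
        assert len(hits) == 1  # strong homolog retained
        ev = hits[0].evalue
        assert ev <= 1e-5
        # exact-boundary semantics: candidate at the cutoff is retained
        cfg = SearchConfig(evalue_cutoff=ev, Z=1)
        assert len(search(calibrated, [homolog], cfg)) == 1

    def test_hits_sorted_and_shrink_with_cutoff(self, calibrated):
        rng = np.random.default_rng(12)
        consensus = "".join(AA_ORDER[i] for i in calibrated.match_emit.argmax(axis=1))
        targets = [consensus] + [random_peptide(rng, 30) for _ in range(20)]
        loose = search(calibrated, targets, SearchConfig(evalue_cutoff=10.0))
        tight = search(calibrated, targets, SearchConfig(evalue_cutoff=1e-5))
        evs = [h.evalue for h in loose]
        assert evs == sorted(evs)
        assert {h.target_id for h in tight} <= {h.target_id for h in loose}

    def test_empty_target_list_ok(self, calibrated):
        assert search(calibrated, [], SearchConfig()) == []

    def test_provenance_copied_from_frames(self, calibrated):
        from hmmscreen import seqio
        from hmmscreen.synthetic_data import reverse_translate

        consensus = "".join(AA_ORDER[i] for i in calibrated.match_emit.argmax(axis=1))
        prot = seqio.SequenceRecord(id="p", residues=consensus, alphabet=seqio.PROTEIN)
        dna = reverse_translate(prot, 0.5, seed=1)
        dna = seqio.SequenceRecord(id="ctg", residues=dna.residues, alphabet=seqio.DNA)
        frames = seqio.six_frame_translate(dna, min_peptide_len=5)
        hits = search(calibrated, frames, SearchConfig(evalue_cutoff=1e-3))
        assert hits, "implanted consensus must be found"
        best = hits[0]
        assert best.contig_id == "ctg" and best.frame == 1
        assert best.nt_start == 1 and best.nt_end == 3 * len(consensus)

    def test_background_evalues_roughly_uniform(self, calibrated):
        rng = np.random.default_rng(13)
        peps = [random_peptide(rng, 50) for _ in range(400)]
        scores = forward_scores(calibrated, peps)
        evs = [evalue_of(float(s), calibrated.calibration, 400) for s in scores]
        stat = se.evalue_uniformity_check(evs, 400)
        assert 0 <= stat <= 1  # diagnostic only; deviations warn, never fail
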