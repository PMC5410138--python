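"""Standing benchmark experiments with a single seed-derivation policy.

Every experiment here regenerates its inputs from scratch as a pure
function of one master seed, runs the toolkit, and returns plain
numbers.  The test suite asserts tolerance bands on these numbers; the
acceptance script reports them verbatim.  Keeping both on one code path
guarantees that what is tested is what is reported.

The exhaustive path-enumeration scorer in this module is intentionally
independent of the dynamic-programming engine it checks: it sums the
probability of every admissible local alignment explicitly.
"""

from __future__ import annotations

import itertools
import math
import pathlib
import tempfile

import numpy as np

from . import profile_build as pb
from . import screen_pipeline as sp
from . import search_engine as se
from . import seqio
from . import synthetic_data as sd
from . import validation as va


def random_small_model(rng: np.random.Generator, M: int) -> pb.ProfileHMM:
    """A fully random valid profile, for oracle comparisons."""
    match_emit = rng.dirichlet(np.ones(20) * 0.5, size=M)
    insert_emit = rng.dirichlet(np.ones(20), size=M + 1)
    transitions = np.zeros((M + 1, 7))
    transitions[:, 0:3] = rng.dirichlet(np.ones(3), size=M + 1)
    transitions[:, 3:5] = rng.dirichlet(np.ones(2), size=M + 1)
    transitions[:, 5:7] = rng.dirichlet(np.ones(2), size=M + 1)
    background = rng.dirichlet(np.ones(20) * 5)
    return pb.ProfileHMM("random", match_emit, insert_emit, transitions, background)


def enumerate_alignment_weights(model: pb.ProfileHMM, peptide: str) -> list[float]:
    """Probability-space weight of every local alignment, by brute force."""
    M, L = model.M, len(peptide)
    res = [pb.AA_INDEX.get(a) for a in peptide]
    bg, t = model.background, model.transitions

    def emr(k, i):
        a = res[i - 1]
        return 1.0 if a is None else model.match_emit[k - 1][a] / bg[a]

    def insr(k, i):
        a = res[i - 1]
        return 1.0 if a is None else model.insert_emit[k][a] / bg[a]

    def texit(k):
        return 1.0 / (M - k + 1)

    weights: list[float] = []

    def from_match(k, i, w):
        weights.append(w * texit(k))
        stay = 1.0 - texit(k)
        if k < M:
            if i < L:
                from_match(k + 1, i + 1, w * stay * t[k][0] * emr(k + 1, i + 1))
                from_insert(k, i + 1, w * stay * t[k][1] * insr(k, i + 1))
            from_delete(k + 1, i, w * stay * t[k][2])

    def from_insert(k, i, w):
        if i < L:
            from_match(k + 1, i + 1, w * t[k][3] * emr(k + 1, i + 1))
            from_insert(k, i + 1, w * t[k][4] * insr(k, i + 1))

    def from_delete(k, i, w):
        if k < M:
            if i < L:
                from_match(k + 1, i + 1, w * t[k][5] * emr(k + 1, i + 1))
            from_delete(k + 1, i, w * t[k][6])

    for i0 in range(1, L + 1):
        for j in range(1, M + 1):
            from_match(j, i0, emr(j, i0) / (M * L))
    return weights


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (tie-free)."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), len(x))]
    p_le = sum(1 for s in sums if s <= w_obs) / len(sums)
    p_ge = sum(1 for s in sums if s >= w_obs) / len(sums)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Experiments.  Each takes the master seed and derives its own sub-seeds.
# ---------------------------------------------------------------------------

def oracle_agreement(master_seed: int, n_models: int = 100) -> dict:
    """Worst |DP - enumeration| over random small models and short peptides."""
    rng = np.random.default_rng(master_seed)
    worst_f = worst_v = 0.0
    for _ in range(n_models):
        model = random_small_model(rng, int(rng.integers(1, 4)))
        pep = "".join(rng.choice(list(pb.AA_ORDER + "X"), size=int(rng.integers(1, 5))))
        weights = enumerate_alignment_weights(model, pep)
        worst_f = max(worst_f, abs(se.forward_score(model, pep) - math.log2(sum(weights))))
        v, _ = se.viterbi_align(model, pep)
        worst_v = max(worst_v, abs(v - math.log2(max(weights))))
    return {
        "forward_oracle_max_abs_diff_bits": {"value": worst_f, "n": n_models},
        "viterbi_oracle_max_abs_diff_bits": {"value": worst_v, "n": n_models},
    }


def parameter_recovery(master_seed: int, n_samples: int = 2000) -> dict:
    """Max per-row total-variation error of rebuilt match emissions.

    Samples are i.i.d. draws from the ground-truth profile, so the
    rebuild uses uniform sequence weights.
    """
    truth = sd.random_profile(10, seed=master_seed + 1000)
    msa = sd.sample_msa_from_profile(truth, n_samples, seed=master_seed + 1001)
    model = pb.build_profile(msa, pb.BuildConfig(), reweight=False)
    if model.M != truth.M:
        return {"emission_recovery_max_tv": {"value": 1.0, "n": n_samples}}
    tv = 0.5 * np.abs(model.match_emit - truth.match_emit).sum(axis=1)
    return {"emission_recovery_max_tv": {"value": float(tv.max()), "n": n_samples}}


def calibration_accuracy(
    master_seed: int, n_targets: int = 10000, n_seeds: int = 20
) -> dict:
    """Mean background hit count at E <= t for t in {0.1, 1, 10}.

    Well-calibrated E-values make the mean count approximately t.
    """
    model = sd.random_profile(10, seed=master_seed + 2000)
    se.calibrate(
        model, n_random=20000, length_dist=(100.0, 3.0),
        seed=master_seed + 2001, tail_fraction=0.005,
    )
    counts: dict[float, list[int]] = {0.1: [], 1.0: [], 10.0: []}
    for s in range(n_seeds):
        rng = np.random.default_rng(master_seed + 2100 + s)
        lengths = np.maximum(
            5, np.round(rng.gamma(3.0, 100 / 3.0, size=n_targets))
        ).astype(int)
        peps = [
            "".join(rng.choice(list(pb.AA_ORDER), size=L, p=model.background))
            for L in lengths
        ]
        scores = se.forward_scores(model, peps)
        evs = np.array(
            [se.evalue_of(float(x), model.calibration, n_targets) for x in scores]
        )
        for t in counts:
            counts[t].append(int((evs <= t).sum()))
    return {
        f"background_hits_at_evalue_{t:g}": {"value": float(np.mean(v)), "n": n_targets}
        for t, v in counts.items()
    }


def family_model(master_seed: int):
    """Ancestor + calibrated profile of a 30-member synthetic family."""
    ancestor, family = sd.make_family(
        length=250, n=30, divergence=0.2, seed=master_seed + 3000
    )
    model = pb.build_profile(sd.family_alignment(family), name="family")
    se.calibrate(model, n_random=2000, length_dist=(100.0, 3.0), seed=master_seed + 3001)
    return ancestor, model


def synthetic_screen(master_seed: int, ancestor, model) -> dict:
    """5 implanted homologs at 20% divergence among 20 contigs."""
    implants = [sd.diverge(ancestor, 0.2, seed=master_seed + 4000 + i) for i in range(5)]
    for i, p in enumerate(implants):
        p.id = f"implant{i}"
    cfg = sd.SimConfig(
        seed=master_seed + 4100, n_contigs=20, contig_length_mean=5000,
        implant_positions=[(2 * i, 1000, (-1) ** i, i) for i in range(5)],
    )
    contigs, truth = sd.make_metagenome(cfg, implants)
    _, hits = sp.screen_sample(
        model, contigs, site="Stool",
        search_config=se.SearchConfig(evalue_cutoff=1e-5), sample_id="bench",
    )
    truth_contigs = set(truth.contig_id)
    detected = sum(1 for h in hits if h.contig_id in truth_contigs)
    false_pos = sum(1 for h in hits if h.contig_id not in truth_contigs)
    return {
        "synthetic_screen_implants_detected": {"value": detected, "n": 5},
        "synthetic_screen_false_positives": {"value": false_pos, "n": 20},
    }


def validation_mirror(master_seed: int, ancestor, model) -> dict:
    """9 synthetic producers vs 7 far-diverged non-producers."""
    controls = []
    for i in range(9):
        pos = sd.diverge(ancestor, 0.2, seed=master_seed + 5000 + i)
        pos.id = f"pos{i}"
        controls.append(
            va.ControlRecord(
                f"producer{i}", "LanB",
                [sd.reverse_translate(pos, 0.45, seed=master_seed + 5100 + i)],
            )
        )
    for i in range(7):
        neg = sd.diverge(ancestor, 0.9, seed=master_seed + 5200 + i)
        neg.id = f"neg{i}"
        controls.append(
            va.ControlRecord(
                f"nonproducer{i}", "LanM",
                [sd.reverse_translate(neg, 0.45, seed=master_seed + 5300 + i)],
            )
        )
    report = va.validate(model, controls, se.SearchConfig(evalue_cutoff=1e-5))
    return {
        "validation_sensitivity": {"value": report.sensitivity, "n": 9},
        "validation_specificity": {"value": report.specificity, "n": 7},
    }


def ranksum_checks(master_seed: int) -> dict:
    """Toy exact p plus worst deviation from enumeration over n<=8 layouts."""
    toy = sp.compare_densities([1, 2], [3, 4]).p_value
    rng = np.random.default_rng(master_seed + 6000)
    worst, layouts = 0.0, 0
    for na in range(2, 5):
        for nb in range(2, 9 - na):
            for _ in range(6):
                vals = rng.permutation(rng.uniform(0, 1, na + nb))
                x, y = list(vals[:na]), list(vals[na:])
                worst = max(
                    worst,
                    abs(sp.compare_densities(x, y).p_value - exact_ranksum_p(x, y)),
                )
                layouts += 1
    return {
        "wilcoxon_toy_two_sided_p": {"value": toy, "n": 4},
        "wilcoxon_exact_max_abs_error": {"value": worst, "n": layouts},
    }


def round_trips(master_seed: int) -> dict:
    """FASTA/profile round-trip fidelity and translation coordinate checks."""
    rng = np.random.default_rng(master_seed + 7000)
    model = sd.random_profile(10, seed=master_seed + 7001)
    se.calibrate(model, n_random=300, seed=master_seed + 7002)
    records = [
        seqio.SequenceRecord(
            id=f"c{i}",
            residues="".join(rng.choice(list("ACGTN"), size=int(rng.integers(30, 200)))),
            alphabet=seqio.DNA,
        )
        for i in range(10)
    ]
    with tempfile.TemporaryDirectory() as tmp:
        tmp = pathlib.Path(tmp)
        fasta = tmp / "rt.fna"
        seqio.write_fasta(records, fasta)
        back = seqio.read_fasta(fasta, alphabet=seqio.DNA)
        fasta_mismatches = sum(
            (a.id, a.residues) != (b.id, b.residues) for a, b in zip(back, records)
        )
        hmm = tmp / "rt.hmm"
        pb.write_profile(model, hmm)
        again = pb.read_profile(hmm)
        max_diff = max(
            float(np.abs(again.match_emit - model.match_emit).max()),
            float(np.abs(again.insert_emit - model.insert_emit).max()),
            float(np.abs(again.transitions - model.transitions).max()),
        )
    violations = n_segments = 0
    for rec in records:
        for seg in seqio.six_frame_translate(rec, min_peptide_len=1):
            n_segments += 1
            if seg.nt_end - seg.nt_start + 1 != 3 * len(seg.peptide):
                violations += 1
                continue
            sub = seqio.SequenceRecord(
                id="s", residues=rec.residues[seg.nt_start - 1 : seg.nt_end],
                alphabet=seqio.DNA,
            )
            if seg.frame < 0:
                sub = seqio.reverse_complement(sub)
            (reseg,) = seqio.translate_frame(sub, 1, min_peptide_len=1)
            if reseg.peptide != seg.peptide:
                violations += 1
    return {
        "fasta_roundtrip_mismatches": {"value": fasta_mismatches, "n": len(records)},
        "profile_roundtrip_max_abs_diff": {"value": max_diff, "n": model.M},
        "translation_coordinate_violations": {"value": violations, "n": n_segments},
    }


def density_ratio() -> dict:
    """7 reference-genome hits over the implied database size, in hits/Mb."""
    db_mb = 7 / 0.006
    summary = sp.SampleSummary("refgenomes", "Stool", n_hits=7, assembly_mb=db_mb)
    table = sp.density_table([summary])
    return {
        "genomic_screen_hits_per_mb": {
            "value": round(float(table.loc["Stool", "mean_density"]), 3),
            "n": 7,
        }
    }


def run_all(master_seed: int) -> dict:
    results: dict = {}
    results.update(oracle_agreement(master_seed))
    results.update(parameter_recovery(master_seed))
    results.update(calibration_accuracy(master_seed))
    ancestor, model = family_model(master_seed)
    results.update(synthetic_screen(master_seed, ancestor, model))
    results.update(validation_mirror(master_seed, ancestor, model))
    results.update(ranksum_checks(master_seed))
    results.update(round_trips(master_seed))
    results.update(density_ratio())
    return results
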