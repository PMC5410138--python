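"""Local-alignment scoring of peptides against a profile HMM.

Both the forward (sum over alignments) and Viterbi (best alignment)
scores are log-odds in bits against an i.i.d. background null.  Local
alignment is modelled probabilistically: an alignment starts at any
residue position i and any match state j with entry mass 1/(M*L), runs
through the match/insert/delete core, and leaves from match state k with
exit probability 1/(M-k+1) — which makes the exit point uniform over the
match states at or after the entry point, and keeps the total path mass
at most 1.  Flanking residues are emitted by the background in both the
model and the null, so they cancel; unknown residues (X) likewise emit
background on both sides and are score-neutral.

Scores are converted to E-values through a Gumbel law calibrated on
random background peptides.  The default calibration fits an
exponential upper tail (the Gumbel tail regime) to the exceedances over
a high score threshold, estimating both the slope lambda and the
location mu from the calibration scores; a full maximum-likelihood
Gumbel fit and a lambda = ln 2 pinned variant (the asymptotic
likelihood-ratio bound in bits) are available as alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from .profile_build import AA_INDEX, AA_ORDER, GumbelParams, ProfileHMM
from .seqio import PROTEIN, SequenceRecord, TranslatedFrame

LN2 = math.log(2.0)
_NEG = -np.inf
_MIN_EVALUE = 1e-300


class CalibrationError(RuntimeError):
    """Degenerate calibration or model searched without calibration."""


@dataclass
class SearchConfig:
    """Search-time settings.

    Z is the effective database size used in E = Z * P(score); it
    defaults to the number of segments actually searched, mimicking a
    per-sample run of a conventional profile search.
    """

    evalue_cutoff: float = 1e-5
    Z: int | None = None
    score_kind: str = "forward"
    seed: int = 0
    min_peptide_len: int = 20

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.Z is not None and self.Z < 1:
            raise ValueError("Z must be >= 1")
        if self.score_kind not in ("forward", "viterbi"):
            raise ValueError("score_kind must be 'forward' or 'viterbi'")


@dataclass
class Hit:
    """A thresholded match of a profile to one target peptide segment."""

    model_name: str
    target_id: str
    bit_score: float
    evalue: float
    ali_start: int
    ali_end: int
    contig_id: str | None = None
    frame: int | None = None
    nt_start: int | None = None
    nt_end: int | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if not 1 <= self.ali_start <= self.ali_end:
            raise ValueError("alignment coordinates must satisfy 1 <= start <= end")


class _ScoringModel:
    """Log-space parameterization of the local-alignment model."""

    def __init__(self, model: ProfileHMM):
        M = model.M
        self.M = M
        with np.errstate(divide="ignore"):
            lbg = np.log(model.background)
            # emission log-odds with an extra X column (score-neutral)
            self.lmatch = np.hstack(
                [np.log(model.match_emit) - lbg, np.zeros((M, 1))]
            )
            self.lins = np.hstack(
                [np.log(model.insert_emit) - lbg, np.zeros((M + 1, 1))]
            )
            t = np.log(model.transitions)
        # exit probability from match state k (1-based): uniform end point
        texit = 1.0 / (M - np.arange(1, M + 1) + 1.0)
        self.ltexit = np.log(texit)
        with np.errstate(divide="ignore"):
            lstay = np.log1p(-texit)  # -inf at k = M
        # transitions out of position k (index k-1 for k = 1..M)
        self.a_MM = lstay + t[1:, 0]
        self.a_MI = lstay + t[1:, 1]
        self.a_MD = lstay + t[1:, 2]
        self.a_IM = t[1:, 3]
        self.a_II = t[1:, 4]
        self.a_DM = t[1:, 5]
        self.a_DD = t[1:, 6]


def encode_peptides(peptides: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode peptides (X and unknowns -> 20), padded with -1."""
    lengths = np.array([len(p) for p in peptides], dtype=int)
    if len(peptides) == 0:
        return np.zeros((0, 0), dtype=np.int8), lengths
    if lengths.min() == 0:
        raise ValueError("empty peptide")
    enc = np.full((len(peptides), lengths.max()), -1, dtype=np.int8)
    for i, pep in enumerate(peptides):
        enc[i, : len(pep)] = [AA_INDEX.get(a, 20) for a in pep]
    return enc, lengths


def _logaddexp3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


def _batch_scores(model: ProfileHMM, peptides: list[str], kind: str) -> np.ndarray:
    """Forward or Viterbi bit scores for a batch of peptides."""
    if len(peptides) == 0:
        return np.zeros(0)
    sm = _ScoringModel(model)
    M = sm.M
    enc, lengths = encode_peptides(peptides)
    n, Lmax = enc.shape
    entry = -np.log(M) - np.log(lengths)  # log 1/(M*L) per peptide
    forward = kind == "forward"

    VM = np.full((n, M), _NEG)
    VI = np.full((n, M + 1), _NEG)
    VD = np.full((n, M), _NEG)
    total = np.full(n, _NEG)
    for i in range(Lmax):
        active = enc[:, i] >= 0
        res = np.where(active, enc[:, i], 20)
        em = sm.lmatch[:, res].T  # (n, M)
        em[~active] = _NEG
        # match: entry here, or continue from position k-1 states at i-1
        cont = np.full((n, M), _NEG)
        prev_m = VM[:, :-1] + sm.a_MM[:-1]
        prev_i = VI[:, 1:M] + sm.a_IM[:-1]
        prev_d = VD[:, :-1] + sm.a_DM[:-1]
        if forward:
            cont[:, 1:] = _logaddexp3(prev_m, prev_i, prev_d)
            VM_new = em + np.logaddexp(entry[:, None], cont)
        else:
            cont[:, 1:] = np.maximum(np.maximum(prev_m, prev_i), prev_d)
            VM_new = em + np.maximum(entry[:, None], cont)
        # inserts: I_1..I_M fed by M_k -> I_k and I_k self-loop at i-1
        emi = sm.lins[1:, res].T
        emi[~active] = _NEG
        from_m = VM + sm.a_MI
        from_i = VI[:, 1:] + sm.a_II
        if forward:
            VI_new = np.hstack(
                [np.full((n, 1), _NEG), emi + np.logaddexp(from_m, from_i)]
            )
        else:
            VI_new = np.hstack(
                [np.full((n, 1), _NEG), emi + np.maximum(from_m, from_i)]
            )
        # deletes: same residue index, scan along k
        VD_new = np.full((n, M), _NEG)
        for k in range(1, M):
            from_m = VM_new[:, k - 1] + sm.a_MD[k - 1]
            from_d = VD_new[:, k - 1] + sm.a_DD[k - 1]
            VD_new[:, k] = (
                np.logaddexp(from_m, from_d) if forward else np.maximum(from_m, from_d)
            )
        VM, VI, VD = VM_new, VI_new, VD_new
        ends = VM + sm.ltexit
        if forward:
            step = np.logaddexp.reduce(ends, axis=1)
            total = np.logaddexp(total, np.where(active, step, _NEG))
        else:
            step = ends.max(axis=1)
            total = np.maximum(total, np.where(active, step, _NEG))
    return total / LN2


def forward_scores(model: ProfileHMM, peptides: list[str]) -> np.ndarray:
    return _batch_scores(model, peptides, "forward")


def viterbi_scores(model: ProfileHMM, peptides: list[str]) -> np.ndarray:
    return _batch_scores(model, peptides, "viterbi")


def forward_score(model: ProfileHMM, peptide: str) -> float:
    """Log2 sum over all local alignments of path odds against background."""
    if not peptide:
        raise ValueError("empty peptide")
    return float(forward_scores(model, [peptide])[0])


def viterbi_align(model: ProfileHMM, peptide: str):
    """Best local alignment.

    Returns ``(bit_score, path)`` where path is a list of
    ``(state, position, residue_index)`` triples; residue_index is the
    1-based peptide coordinate for M/I states and the coordinate of the
    preceding emission for D states.  Ties break by state preference
    M > D > I, then smaller position.
    """
    if not peptide:
        raise ValueError("empty peptide")
    sm = _ScoringModel(model)
    M = sm.M
    L = len(peptide)
    res = [AA_INDEX.get(a, 20) for a in peptide]
    entry = -math.log(M) - math.log(L)

    VM = np.full((L + 1, M + 1), _NEG)
    VI = np.full((L + 1, M + 1), _NEG)
    VD = np.full((L + 1, M + 1), _NEG)
    ptr_m = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 entry, 1 M, 2 D, 3 I
    ptr_i = np.zeros((L + 1, M + 1), dtype=np.int8)  # 1 M, 3 I
    ptr_d = np.zeros((L + 1, M + 1), dtype=np.int8)  # 1 M, 2 D
    for i in range(1, L + 1):
        x = res[i - 1]
        for k in range(1, M + 1):
            # candidates in tie preference order: entry, M, D, I
            best, arg = entry, 0
            if k > 1:
                cand = VM[i - 1, k - 1] + sm.a_MM[k - 2]
                if cand > best:
                    best, arg = cand, 1
                cand = VD[i - 1, k - 1] + sm.a_DM[k - 2]
                if cand > best:
                    best, arg = cand, 2
                cand = VI[i - 1, k - 1] + sm.a_IM[k - 2]
                if cand > best:
                    best, arg = cand, 3
            VM[i, k] = sm.lmatch[k - 1, x] + best
            ptr_m[i, k] = arg
            fm = VM[i - 1, k] + sm.a_MI[k - 1]
            fi = VI[i - 1, k] + sm.a_II[k - 1]
            VI[i, k] = sm.lins[k, x] + max(fm, fi)
            ptr_i[i, k] = 1 if fm >= fi else 3
        for k in range(2, M + 1):
            fm = VM[i, k - 1] + sm.a_MD[k - 2]
            fd = VD[i, k - 1] + sm.a_DD[k - 2]
            VD[i, k] = max(fm, fd)
            ptr_d[i, k] = 1 if fm >= fd else 2
    ends = VM[1:, 1:] + sm.ltexit[None, :]
    best_flat = int(np.argmax(ends))
    i_end, k_end = best_flat // M + 1, best_flat % M + 1
    score = ends[i_end - 1, k_end - 1] / LN2

    path = []
    state, i, k = "M", i_end, k_end
    while True:
        path.append((state, k, i))
        if state == "M":
            arg = ptr_m[i, k]
            if arg == 0:
                break
            state = {1: "M", 2: "D", 3: "I"}[int(arg)]
            i, k = i - 1, k - 1
        elif state == "I":
            state = "M" if ptr_i[i, k] == 1 else "I"
            i = i - 1
        else:  # D
            state = "M" if ptr_d[i, k] == 1 else "D"
            k = k - 1
    path.reverse()
    return float(score), path


def alignment_bounds(path) -> tuple[int, int]:
    """1-based peptide coordinates of the first and last emitted residue."""
    emitted = [i for state, _, i in path if state in ("M", "I")]
    return emitted[0], emitted[-1]


def calibrate(
    model: ProfileHMM,
    n_random: int = 1000,
    length_dist: tuple[float, float] = (100.0, 3.0),
    seed: int = 0,
    score_kind: str = "forward",
    fit: str = "tail",
    tail_fraction: float = 0.01,
) -> GumbelParams:
    """Calibrate the score-to-E-value map on random background peptides.

    Peptide lengths follow a gamma law with the given (mean, shape);
    residues are i.i.d. from the model background.  ``fit`` selects the
    estimator: ``"tail"`` (default) fits an exponential law to the score
    exceedances over the upper ``tail_fraction`` quantile (lambda from
    the mean excess, mu from the exceedance rate), ``"tail_ln2"`` pins
    lambda to ln 2 and fits mu alone, and ``"gumbel_ml"`` is a full
    Gumbel maximum-likelihood fit.  The result is stored on
    ``model.calibration``.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    mean_len, shape = length_dist
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        5, np.round(rng.gamma(shape, mean_len / shape, size=n_random))
    ).astype(int)
    bg = model.background
    peptides = [
        "".join(rng.choice(list(AA_ORDER), size=L, p=bg)) for L in lengths
    ]
    scores = _batch_scores(model, peptides, score_kind)
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate calibration score distribution")
    if fit == "gumbel_ml":
        loc, scale = gumbel_r.fit(scores)
        params = GumbelParams(mu=float(loc), lam=1.0 / float(scale),
                              n_calibration=n_random, seed=seed)
    elif fit in ("tail", "tail_ln2"):
        # at least 25 exceedances so the slope estimate stays usable at small n
        m = min(n_random - 1, max(25, int(round(n_random * tail_fraction))))
        order = np.sort(scores)
        s0 = float(order[n_random - m - 1])
        excess = scores[scores > s0] - s0
        if len(excess) < 5 or excess.mean() <= 0:
            raise CalibrationError("degenerate score tail; cannot calibrate")
        lam = LN2 if fit == "tail_ln2" else 1.0 / float(excess.mean())
        mu = s0 + math.log(len(excess) / n_random) / lam
        params = GumbelParams(mu=mu, lam=lam, n_calibration=n_random, seed=seed)
    else:
        raise ValueError(f"unknown fit {fit!r}")
    model.calibration = params
    return params


def evalue_of(score: float, gumbel: GumbelParams | None, Z: int) -> float:
    """E = Z * P(Gumbel >= score); strictly decreasing in score."""
    if gumbel is None:
        raise CalibrationError("model is not calibrated; run calibrate() first")
    if Z < 1:
        raise ValueError("Z must be >= 1")
    x = gumbel.lam * (score - gumbel.mu)
    if x > 30:  # survival ~ exp(-x); avoid cancellation in expm1 path
        ev = Z * math.exp(-x) if x < 690 else 0.0
    else:
        ev = Z * -math.expm1(-math.exp(-x))
    return max(ev, _MIN_EVALUE)


def evalue_uniformity_check(evalues, Z: int) -> float:
    """Kolmogorov-Smirnov distance of E-values from uniform(0, Z).

    For background targets, well-calibrated E-values are approximately
    uniform on (0, Z).  Emits a (non-blocking) warning when the KS test
    rejects at the 1% level; returns the KS statistic.
    """
    import warnings

    from scipy.stats import kstest, uniform

    evalues = np.asarray(list(evalues), dtype=float)
    res = kstest(evalues, uniform(loc=0, scale=Z).cdf)
    if res.pvalue < 0.01:
        warnings.warn(
            f"E-values deviate from uniform(0, {Z}): KS={res.statistic:.3f}, "
            f"p={res.pvalue:.2g} (calibration is tail-oriented; body deviation "
            "is expected and harmless for thresholded searches)"
        )
    return float(res.statistic)


def _target_parts(target):
    if isinstance(target, TranslatedFrame):
        return target.peptide, target.provenance_id, target
    if isinstance(target, SequenceRecord):
        return target.residues, target.id, None
    return str(target), str(target), None


def search(model: ProfileHMM, targets, config: SearchConfig | None = None) -> list[Hit]:
    """Score every target, keep hits with E-value <= cutoff (inclusive).

    One candidate per target (its best local alignment); hits come back
    sorted by ascending E-value.  Provenance fields are copied from
    TranslatedFrame targets.
    """
    config = config or SearchConfig()
    if model.calibration is None:
        raise CalibrationError("model is not calibrated; run calibrate() first")
    targets = list(targets)
    if not targets:
        return []
    parts = [_target_parts(t) for t in targets]
    peptides = [p[0] for p in parts]
    Z = config.Z if config.Z is not None else len(targets)
    scores = _batch_scores(model, peptides, config.score_kind)
    hits: list[Hit] = []
    for (pep, tid, frame), score in zip(parts, scores):
        ev = evalue_of(float(score), model.calibration, Z)
        if ev <= config.evalue_cutoff:
            _, path = viterbi_align(model, pep)
            a, b = alignment_bounds(path)
            hits.append(
                Hit(
                    model_name=model.name,
                    target_id=tid,
                    bit_score=float(score),
                    evalue=ev,
                    ali_start=a,
                    ali_end=b,
                    contig_id=frame.contig_id if frame else None,
                    frame=frame.frame if frame else None,
                    nt_start=frame.nt_start if frame else None,
                    nt_end=frame.nt_end if frame else None,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.target_id))
    return hits
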