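"""Profile HMM construction from a protein multiple sequence alignment.

The model follows the classic left-to-right architecture: one match state
per sufficiently occupied alignment column, with an insert state after
each match position (plus an N-terminal insert) and a delete state per
position.  Parameters are estimated from Henikoff position-weighted
counts with background-proportional pseudocounts, so every probability is
strictly positive and every stochastic row sums to one.

Transition rows are stored per position k = 0..M in the fixed order
(M->M, M->I, M->D, I->M, I->I, D->M, D->D), where the three source-state
groups each sum to 1.  Row 0 holds the begin-state transitions and row M
the transitions into the (implicit) end state.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import FastaParseError, _iter_fasta

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP_CHARS = frozenset("-.")
TRANSITION_ORDER = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANSITION_ORDER)}
_GROUPS = ((0, 1, 2), (3, 4), (5, 6))  # M-, I- and D-source transition groups


class AlignmentError(ValueError):
    """Raised for structurally invalid multiple alignments."""


class BuildError(ValueError):
    """Raised when a profile cannot be built from the given alignment."""


class ProfileFormatError(ValueError):
    """Malformed profile file; message names the line."""


@dataclass
class MultipleAlignment:
    """Equal-length gapped protein sequences with per-sequence weights.

    Weights are non-negative and by convention sum to the number of
    sequences; fresh alignments start with unit weights.
    """

    ids: list[str]
    rows: list[str]
    weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        n_cols = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n_cols:
                raise AlignmentError(
                    f"record {sid!r} has length {len(row)}, expected {n_cols}"
                )
        if self.weights is None:
            self.weights = np.ones(len(self.rows))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.rows):
            raise AlignmentError("one weight per sequence required")
        if not np.all(self.weights > 0):
            raise AlignmentError("weights must be strictly positive")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.rows]


@dataclass
class BuildConfig:
    """Knobs for model construction.

    occupancy_threshold: a column becomes a match column when its weighted
        non-gap fraction is >= this value (boundary inclusive).
    pseudocount_alpha: total pseudocount mass added to each emission
        distribution, spread in proportion to the background; transition
        rows get alpha/7 per transition type.
    background: "flat" (0.05 per residue), "empirical" (training-set
        frequencies), or an explicit 20-vector.
    """

    occupancy_threshold: float = 0.5
    pseudocount_alpha: float = 1.0
    background: object = "flat"
    min_match_states: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.occupancy_threshold <= 1:
            raise ValueError("occupancy_threshold must be in (0, 1]")
        if self.pseudocount_alpha <= 0:
            raise ValueError("pseudocount_alpha must be positive")
        if self.min_match_states < 1:
            raise ValueError("min_match_states must be positive")

    def background_vector(self, msa: MultipleAlignment | None = None) -> np.ndarray:
        if isinstance(self.background, str):
            if self.background == "flat":
                return np.full(20, 0.05)
            if self.background == "empirical":
                if msa is None:
                    raise ValueError("empirical background needs an alignment")
                counts = np.zeros(20)
                for row, w in zip(msa.rows, msa.weights):
                    for ch in row:
                        idx = AA_INDEX.get(ch)
                        if idx is not None:
                            counts[idx] += w
                if counts.sum() == 0:
                    raise BuildError("alignment has no countable residues")
                return counts / counts.sum()
            raise ValueError(f"unknown background {self.background!r}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be a positive 20-vector summing to 1")
        return bg


@dataclass
class GumbelParams:
    """Gumbel location/scale calibrated from random-sequence scores (bits)."""

    mu: float
    lam: float
    n_calibration: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.n_calibration < 100:
            raise ValueError("calibration needs at least 100 random sequences")


@dataclass
class ProfileHMM:
    """A calibratable protein profile HMM.

    match_emit: (M, 20) row-stochastic; insert_emit: (M+1, 20) for inserts
    I_0..I_M; transitions: (M+1, 7) in TRANSITION_ORDER with the three
    source groups each summing to 1.
    """

    name: str
    match_emit: np.ndarray
    insert_emit: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    calibration: GumbelParams | None = None

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        M = self.match_emit.shape[0]
        if M < 1:
            raise ValueError("model needs at least one match state")
        if self.match_emit.shape != (M, 20):
            raise ValueError("match_emit must be (M, 20)")
        if self.insert_emit.shape != (M + 1, 20):
            raise ValueError("insert_emit must be (M+1, 20)")
        if self.transitions.shape != (M + 1, 7):
            raise ValueError("transitions must be (M+1, 7)")
        for arr, what in (
            (self.match_emit, "match emission"),
            (self.insert_emit, "insert emission"),
        ):
            if np.any(arr <= 0):
                raise ValueError(f"zero {what} probability (pseudocounting missing?)")
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError(f"{what} rows must sum to 1")
        if np.any(self.transitions <= 0):
            raise ValueError("zero transition probability (pseudocounting missing?)")
        for group in _GROUPS:
            sums = self.transitions[:, group].sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > 1e-9:
                raise ValueError("each transition source group must sum to 1")
        if self.background.shape != (20,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be a 20-vector summing to 1")

    @property
    def M(self) -> int:
        return self.match_emit.shape[0]


def read_aligned_fasta(path) -> MultipleAlignment:
    """Read an aligned FASTA ('-' and '.' are both gaps) with unit weights."""
    ids, rows = [], []
    with open(path) as handle:
        for header, residues, lineno in _iter_fasta(handle):
            sid = header.split(None, 1)[0]
            row = residues.upper().replace(".", "-")
            bad = set(row) - set(AA_ORDER) - {"-", "X"}
            if bad:
                raise FastaParseError(
                    f"line {lineno}: record {sid!r} contains illegal characters {sorted(bad)}"
                )
            ids.append(sid)
            rows.append(row)
    return MultipleAlignment(ids=ids, rows=rows)


def position_weights(msa: MultipleAlignment, min_occupancy: float = 0.5) -> MultipleAlignment:
    """Henikoff position-based sequence weights, normalized to sum n_seqs.

    In each column, a residue type carried by s of the sequences in a
    column with r distinct types contributes 1/(r*s) to each of those
    sequences.  Columns whose non-gap occupancy is below
    ``min_occupancy`` (majority-gap insert columns) are skipped: a
    rarely occupied column would otherwise hand its lone carriers an
    entire column's worth of weight, badly distorting the profile.
    Gap-only columns are always skipped.
    """
    raw = np.zeros(msa.n_seqs)
    occ_floor = min_occupancy * msa.n_seqs
    for c in range(msa.n_cols):
        col = msa.column(c)
        if sum(ch not in GAP_CHARS for ch in col) < occ_floor:
            continue
        carriers: dict[str, list[int]] = {}
        for i, ch in enumerate(col):
            if ch not in GAP_CHARS:
                carriers.setdefault(ch, []).append(i)
        r = len(carriers)
        if r == 0:
            continue
        for members in carriers.values():
            share = 1.0 / (r * len(members))
            for i in members:
                raw[i] += share
    if np.any(raw == 0):
        empty = [msa.ids[i] for i in np.nonzero(raw == 0)[0]]
        raise AlignmentError(
            f"sequences with no residues in any occupied column cannot be "
            f"weighted: {empty}"
        )
    weights = raw * (msa.n_seqs / raw.sum())
    return MultipleAlignment(ids=list(msa.ids), rows=list(msa.rows), weights=weights)


def assign_match_columns(msa: MultipleAlignment, config: BuildConfig) -> list[str]:
    """Label each column 'match' or 'insert' by weighted non-gap occupancy."""
    total_w = msa.weights.sum()
    labels = []
    for c in range(msa.n_cols):
        occ = sum(
            w for w, row in zip(msa.weights, msa.rows) if row[c] not in GAP_CHARS
        )
        labels.append("match" if occ / total_w >= config.occupancy_threshold else "insert")
    n_match = labels.count("match")
    if n_match < config.min_match_states:
        raise BuildError(
            f"only {n_match} match columns at occupancy threshold "
            f"{config.occupancy_threshold}; lower the threshold or provide a "
            f"deeper alignment (need >= {config.min_match_states})"
        )
    return labels


def _state_path(row: str, labels: list[str]):
    """Yield the (state, position) skeleton path of one aligned sequence."""
    k = 0
    yield ("M", 0)  # begin state treated as match at position 0
    for ch, lab in zip(row, labels):
        if lab == "match":
            k += 1
            yield ("D", k) if ch in GAP_CHARS else ("M", k)
        elif ch not in GAP_CHARS:
            yield ("I", k)
    yield ("M", k + 1)  # end


def build_profile(
    msa: MultipleAlignment,
    config: BuildConfig | None = None,
    name: str = "profile",
    labels: list[str] | None = None,
    reweight: bool = True,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Applies Henikoff weighting (unless ``reweight=False``), assigns match
    columns, then converts weighted observed counts to probabilities:
    match emissions get background-proportional pseudocount mass alpha,
    transitions get alpha/7 per transition type, and insert emissions are
    fixed to the background.
    """
    config = config or BuildConfig()
    if reweight:
        msa = position_weights(msa)
    bg = config.background_vector(msa)
    if labels is None:
        labels = assign_match_columns(msa, config)
    match_cols = [c for c, lab in enumerate(labels) if lab == "match"]
    M = len(match_cols)
    alpha = config.pseudocount_alpha

    emit_counts = np.zeros((M, 20))
    for k, c in enumerate(match_cols):
        for row, w in zip(msa.rows, msa.weights):
            idx = AA_INDEX.get(row[c])
            if idx is not None:  # gaps and X carry no emission count
                emit_counts[k, idx] += w
    match_emit = (emit_counts + alpha * bg) / (
        emit_counts.sum(axis=1, keepdims=True) + alpha
    )

    trans_counts = np.zeros((M + 1, 7))
    for row, w in zip(msa.rows, msa.weights):
        path = list(_state_path(row, labels))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "I" and s2 == "I" and k1 == k2:
                trans_counts[k1, _T["II"]] += w
            else:
                trans_counts[k1, _T[s1 + s2]] += w
    trans_counts += alpha / 7.0
    transitions = trans_counts.copy()
    for group in _GROUPS:
        transitions[:, group] /= transitions[:, group].sum(axis=1, keepdims=True)

    insert_emit = np.tile(bg, (M + 1, 1))
    return ProfileHMM(
        name=name,
        match_emit=match_emit,
        insert_emit=insert_emit,
        transitions=transitions,
        background=bg,
    )


# ---------------------------------------------------------------------------
# Serialization: an ASCII, HMMER3-style dialect.  Probabilities are written
# as negative natural logs with 6 decimals; "//" terminates a model.
# ---------------------------------------------------------------------------

_MAGIC = "PROFILE-HMM/1"


def _fmt(probs) -> str:
    # "+ 0.0" avoids the negative zero that -log(1.0) would print
    return "  ".join(f"{-math.log(p) + 0.0:.6f}" for p in probs)


def write_profile(model: ProfileHMM, path) -> None:
    """Serialize a model (including calibration, if present)."""
    if np.any(model.match_emit <= 0) or np.any(model.transitions <= 0):
        raise ValueError("cannot serialize zero probabilities")
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"NAME  {model.name}\n")
        fh.write(f"LENG  {model.M}\n")
        fh.write(f"ALPH  amino\n")
        if model.calibration is not None:
            c = model.calibration
            fh.write(
                f"STATS GUMBEL {c.mu:.6f} {c.lam:.6f} {c.n_calibration} {c.seed}\n"
            )
        fh.write("BG    " + _fmt(model.background) + "\n")
        fh.write("HMM   " + " ".join(AA_ORDER) + "\n")
        fh.write("      " + " ".join(TRANSITION_ORDER) + "\n")
        for k in range(model.M + 1):
            if k == 0:
                fh.write(f"{k:>5d}  -\n")
            else:
                fh.write(f"{k:>5d}  " + _fmt(model.match_emit[k - 1]) + "\n")
            fh.write("       " + _fmt(model.insert_emit[k]) + "\n")
            fh.write("       " + _fmt(model.transitions[k]) + "\n")
        fh.write("//\n")


def _parse_probs(text: str, n: int, lineno: int) -> np.ndarray:
    parts = text.split()
    if len(parts) != n:
        raise ProfileFormatError(f"line {lineno}: expected {n} values, got {len(parts)}")
    try:
        return np.exp(-np.array([float(p) for p in parts]))
    except ValueError as exc:
        raise ProfileFormatError(f"line {lineno}: {exc}") from exc


def read_profile(path) -> ProfileHMM:
    """Parse a profile written by :func:`write_profile`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line():
        try:
            return next(it)
        except StopIteration:
            raise ProfileFormatError("unexpected end of file") from None

    lineno, line = next_line()
    if line.strip() != _MAGIC:
        raise ProfileFormatError(f"line {lineno}: bad magic {line!r}")
    header: dict[str, str] = {}
    stats = None
    while True:
        lineno, line = next_line()
        if line.startswith("HMM"):
            break
        m = re.match(r"(\S+)\s+(.*)", line)
        if not m:
            raise ProfileFormatError(f"line {lineno}: malformed header line {line!r}")
        header[m.group(1)] = m.group(2).strip()
    for key in ("NAME", "LENG", "BG"):
        if key not in header:
            raise ProfileFormatError(f"missing {key} header line")
    M = int(header["LENG"])
    bg = _parse_probs(header["BG"], 20, 0)
    bg = bg / bg.sum()
    if "STATS" in header:
        parts = header["STATS"].split()
        if len(parts) != 5 or parts[0] != "GUMBEL":
            raise ProfileFormatError("malformed STATS line")
        stats = GumbelParams(
            mu=float(parts[1]), lam=float(parts[2]),
            n_calibration=int(parts[3]), seed=int(parts[4]),
        )
    next_line()  # transition-order comment line
    match_emit = np.zeros((M, 20))
    insert_emit = np.zeros((M + 1, 20))
    transitions = np.zeros((M + 1, 7))
    for k in range(M + 1):
        lineno, line = next_line()
        parts = line.split(None, 1)
        if int(parts[0]) != k:
            raise ProfileFormatError(f"line {lineno}: expected node {k}")
        if k > 0:
            match_emit[k - 1] = _parse_probs(parts[1], 20, lineno)
        lineno, line = next_line()
        insert_emit[k] = _parse_probs(line, 20, lineno)
        lineno, line = next_line()
        transitions[k] = _parse_probs(line, 7, lineno)
    lineno, line = next_line()
    if line.strip() != "//":
        raise ProfileFormatError(f"line {lineno}: missing '//' terminator")
    # renormalize rounding error from the 6-decimal serialization
    match_emit /= match_emit.sum(axis=1, keepdims=True)
    insert_emit /= insert_emit.sum(axis=1, keepdims=True)
    for group in _GROUPS:
        transitions[:, group] /= transitions[:, group].sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=header["NAME"],
        match_emit=match_emit,
        insert_emit=insert_emit,
        transitions=transitions,
        background=bg,
        calibration=stats,
    )
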