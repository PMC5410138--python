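"""Synthetic ground-truth data for every input the pipeline consumes.

Generates protein families from a known profile (or by point-mutating a
random ancestor), decoys at controlled divergence, coding DNA via
GC-biased reverse translation, and metagenome-like contig sets with
implanted family genes plus a truth table.  Everything is a pure
function of (parameters, seed).

The defaults emulate the study conditions at desk scale: a conserved
enzyme family a few hundred residues long, background contigs with
uniform composition at a chosen GC content, and implants placed on
either strand.  Real assemblies additionally carry repeat structure,
uneven coverage and taxon-specific codon usage, none of which is
modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .profile_build import AA_ORDER, MultipleAlignment, ProfileHMM
from .seqio import DNA, PROTEIN, SequenceRecord

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _TABLE1.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE1.stop_codons)

_AA = np.array(list(AA_ORDER))


class SimConfigError(ValueError):
    """Inconsistent simulation configuration (e.g. colliding implants)."""


@dataclass
class SimConfig:
    """Ground-truth layout of one synthetic metagenome sample.

    implant_positions: (contig_index, 0-based offset, strand +1/-1,
    family-member index) for each implanted coding sequence.
    """

    seed: int = 0
    n_family: int = 20
    divergence: float = 0.2
    n_contigs: int = 20
    contig_length_mean: float = 5000.0
    contig_length_dispersion: float = 0.3
    gc_content: float = 0.45
    implant_positions: list[tuple[int, int, int, int]] = field(default_factory=list)
    background_aa_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_family < 1 or self.n_contigs < 1:
            raise SimConfigError("counts must be positive")
        if not 0 <= self.divergence < 1:
            raise SimConfigError("divergence must be in [0, 1)")
        if not 0 < self.gc_content < 1:
            raise SimConfigError("gc_content must be in (0, 1)")
        if self.background_aa_freqs is None:
            self.background_aa_freqs = np.full(20, 0.05)
        self.background_aa_freqs = np.asarray(self.background_aa_freqs, dtype=float)


def random_profile(
    M: int,
    seed: int = 0,
    conservation: float = 0.8,
    t_mm: float = 0.96,
    name: str = "synthetic",
) -> ProfileHMM:
    """A ground-truth profile with one dominant residue per match state.

    Each match state emits a randomly chosen residue with probability
    ``conservation`` and spreads the remainder evenly; transitions favour
    the match-to-match backbone (``t_mm``) with symmetric small insert
    and delete branches.
    """
    rng = np.random.default_rng(seed)
    match_emit = np.full((M, 20), (1.0 - conservation) / 19.0)
    for k, dom in enumerate(rng.integers(0, 20, size=M)):
        match_emit[k, dom] = conservation
    bg = np.full(20, 0.05)
    insert_emit = np.tile(bg, (M + 1, 1))
    branch = (1.0 - t_mm) / 2.0
    row = np.array([t_mm, branch, branch, 0.6, 0.4, 0.6, 0.4])
    transitions = np.tile(row, (M + 1, 1))
    return ProfileHMM(
        name=name,
        match_emit=match_emit,
        insert_emit=insert_emit,
        transitions=transitions,
        background=bg,
    )


def _sample_path(model: ProfileHMM, rng: np.random.Generator):
    """One generative pass begin -> end; returns [(state, pos, residue)]."""
    t = model.transitions
    M = model.M
    path = []
    state, k = "M", 0  # begin
    while True:
        if state == "M":
            probs = t[k, 0:3]
            nxt = ("M", "I", "D")[rng.choice(3, p=probs / probs.sum())]
        elif state == "I":
            probs = t[k, 3:5]
            nxt = ("M", "I")[rng.choice(2, p=probs / probs.sum())]
        else:  # D; at k == M only D->M (end) is possible
            probs = t[k, 5:7]
            nxt = "M" if k == M else ("M", "D")[rng.choice(2, p=probs / probs.sum())]
        if nxt == "I":
            res = _AA[rng.choice(20, p=model.insert_emit[k])]
            path.append(("I", k, res))
        else:
            if k == M:  # transition to the end state
                return path
            k += 1
            if nxt == "M":
                res = _AA[rng.choice(20, p=model.match_emit[k - 1])]
                path.append(("M", k, res))
            else:
                path.append(("D", k, None))
            state = nxt
            continue
        state = "I"


def sample_paths_from_profile(model: ProfileHMM, n: int, seed: int = 0):
    """n i.i.d. state paths with their emitted sequences."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    paths = []
    while len(paths) < n:
        path = _sample_path(model, rng)
        if any(s in ("M", "I") for s, _, _ in path):  # skip empty (all-delete)
            paths.append(path)
    return paths


def sample_from_profile(model: ProfileHMM, n: int, seed: int = 0) -> list[SequenceRecord]:
    """n protein sequences sampled from the generative model."""
    return [
        SequenceRecord(
            id=f"sim{i:05d}",
            residues="".join(r for s, _, r in path if r is not None),
            alphabet=PROTEIN,
        )
        for i, path in enumerate(sample_paths_from_profile(model, n, seed))
    ]


def sample_msa_from_profile(model: ProfileHMM, n: int, seed: int = 0) -> MultipleAlignment:
    """Sampled sequences arranged on their true state-path alignment.

    Match states map to one column each; insert runs after position k map
    to a left-justified block of max-width columns between match columns
    k and k+1.  This is the alignment an ideal aligner would recover, so
    rebuilding a profile from it tests parameter estimation in isolation.
    """
    paths = sample_paths_from_profile(model, n, seed)
    M = model.M
    ins_width = np.zeros(M + 1, dtype=int)
    for path in paths:
        run = np.zeros(M + 1, dtype=int)
        for s, k, _ in path:
            if s == "I":
                run[k] += 1
        ins_width = np.maximum(ins_width, run)
    rows = []
    for path in paths:
        match_res = {k: ("-" if s == "D" else r) for s, k, r in path if s != "I"}
        ins_res: dict[int, list[str]] = {}
        for s, k, r in path:
            if s == "I":
                ins_res.setdefault(k, []).append(r)
        cells = []
        for k in range(M + 1):
            block = ins_res.get(k, [])
            cells.append("".join(block) + "-" * (ins_width[k] - len(block)))
            if k < M:
                cells.append(match_res.get(k + 1, "-"))
        rows.append("".join(cells))
    return MultipleAlignment(ids=[f"sim{i:05d}" for i in range(n)], rows=rows)


def diverge(protein: SequenceRecord, rate: float, seed: int = 0) -> SequenceRecord:
    """Point-mutate each site with probability ``rate`` (uniform targets)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    residues = list(protein.residues)
    for i, aa in enumerate(residues):
        if rng.random() < rate:
            choices = [a for a in AA_ORDER if a != aa]
            residues[i] = choices[rng.integers(0, len(choices))]
    return SequenceRecord(
        id=protein.id, residues="".join(residues), alphabet=PROTEIN,
        description=f"diverged rate={rate}",
    )


def _codon_weights(codons: list[str], gc: float) -> np.ndarray:
    w = []
    for codon in codons:
        p = 1.0
        for base in codon:
            p *= gc / 2.0 if base in "GC" else (1.0 - gc) / 2.0
        w.append(p)
    w = np.array(w)
    return w / w.sum()


def reverse_translate(protein: SequenceRecord, gc_content: float = 0.45, seed: int = 0) -> SequenceRecord:
    """Coding DNA for a protein, codons weighted toward the target GC.

    Translating frame +1 of the output regenerates the protein exactly;
    a stop codon is appended.
    """
    if "X" in protein.residues or "*" in protein.residues:
        raise ValueError("cannot reverse-translate X or stop characters")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein.residues:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.choice(len(options), p=_codon_weights(options, gc_content))])
    codons.append(_STOP_CODONS[rng.choice(3, p=_codon_weights(_STOP_CODONS, gc_content))])
    return SequenceRecord(
        id=protein.id, residues="".join(codons), alphabet=DNA,
        description="reverse-translated",
    )


def make_family(
    length: int = 250,
    n: int = 20,
    divergence: float = 0.2,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """A random ancestor plus n homologs at the given expected divergence."""
    rng = np.random.default_rng(seed)
    bg = np.full(20, 0.05) if background is None else np.asarray(background, float)
    ancestor = SequenceRecord(
        id="ancestor",
        residues="".join(rng.choice(list(AA_ORDER), size=length, p=bg / bg.sum())),
        alphabet=PROTEIN,
    )
    members = [
        SequenceRecord(
            id=f"fam{i:04d}",
            residues=diverge(ancestor, divergence, seed=int(rng.integers(2**31))).residues,
            alphabet=PROTEIN,
        )
        for i in range(n)
    ]
    return ancestor, members


def family_alignment(members: list[SequenceRecord]) -> MultipleAlignment:
    """Equal-length gap-free homologs are trivially their own alignment."""
    return MultipleAlignment(ids=[m.id for m in members], rows=[m.residues for m in members])


def make_metagenome(
    config: SimConfig, family: list[SequenceRecord]
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Background contigs with implanted coding sequences plus truth table.

    The truth table has one row per implant: contig_id, member_id,
    strand, nt_start, nt_end (1-based inclusive, forward strand, stop
    codon included) and protein_len.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    disp = config.contig_length_dispersion
    shape = 1.0 / (disp * disp)
    lengths = np.maximum(
        300, np.round(rng.gamma(shape, config.contig_length_mean / shape, size=config.n_contigs))
    ).astype(int)
    contigs = [
        list("".join(bases[rng.choice(4, size=L, p=base_p)])) for L in lengths
    ]
    used: dict[int, list[tuple[int, int]]] = {}
    truth_rows = []
    for ci, offset, strand, mi in config.implant_positions:
        if not (0 <= ci < config.n_contigs):
            raise SimConfigError(f"implant contig index {ci} out of range")
        if strand not in (1, -1):
            raise SimConfigError("strand must be +1 or -1")
        protein = family[mi]
        cds = reverse_translate(protein, gc, seed=int(rng.integers(2**31))).residues
        if strand == -1:
            cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        start, end = offset, offset + len(cds)  # half-open, 0-based
        if end > lengths[ci]:
            raise SimConfigError(
                f"implant of {protein.id} does not fit contig {ci} "
                f"({end} > {lengths[ci]})"
            )
        for s, e in used.setdefault(ci, []):
            if start < e and s < end:
                raise SimConfigError(f"implant collision on contig {ci}")
        used[ci].append((start, end))
        contigs[ci][start:end] = list(cds)
        truth_rows.append(
            {
                "contig_id": f"contig{ci:04d}",
                "member_id": protein.id,
                "strand": strand,
                "nt_start": start + 1,
                "nt_end": end,
                "protein_len": len(protein),
            }
        )
    records = [
        SequenceRecord(id=f"contig{ci:04d}", residues="".join(c), alphabet=DNA)
        for ci, c in enumerate(contigs)
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig_id", "member_id", "strand", "nt_start", "nt_end", "protein_len"],
    )
    return records, truth
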