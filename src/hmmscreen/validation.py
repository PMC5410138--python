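"""Control-based validation of a profile against labelled strains.

A control is a producer (carries the target dehydratase family, e.g. a
LanB gene) or a non-producer (carries a related but distinct
modification enzyme such as LanM/LanKC/LanL, or nothing).  Detection is
sequence-set-level: a control counts as detected when any translated
segment of its sequences scores at or below the E-value cutoff.  The
report gives per-control verdicts plus sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqio
from .profile_build import ProfileHMM
from .search_engine import SearchConfig, evalue_of, _batch_scores

SUBCLASSES = ("LanB", "LanM", "LanL", "LanKC", "none")


@dataclass
class ControlRecord:
    """One labelled validation strain.

    ``sequence`` may be a FASTA path or a list of SequenceRecords;
    ``alphabet`` is sniffed from the residues when not given.
    """

    strain_label: str
    expected_subclass: str
    sequence: object
    alphabet: str | None = None

    def __post_init__(self) -> None:
        if self.expected_subclass not in SUBCLASSES:
            raise ValueError(
                f"unknown subclass {self.expected_subclass!r}; expected one of {SUBCLASSES}"
            )

    @property
    def is_positive(self) -> bool:
        return self.expected_subclass == "LanB"


@dataclass
class ValidationReport:
    per_control: pd.DataFrame  # strain_label, is_positive, detected, best_evalue
    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int
    errors: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.true_positives / (self.true_positives + self.false_negatives)

    @property
    def specificity(self) -> float:
        return self.true_negatives / (self.true_negatives + self.false_positives)

    def text_grid(self) -> str:
        """Human-readable verdict table."""
        lines = [f"{'Strain':<32} {'Subclass':<8} {'Detected':<9} Best E-value"]
        for _, row in self.per_control.iterrows():
            ev = "-" if np.isnan(row.best_evalue) else f"{row.best_evalue:.3g}"
            lines.append(
                f"{row.strain_label:<32} {row.expected_subclass:<8} "
                f"{'yes' if row.detected else 'no':<9} {ev}"
            )
        lines.append(
            f"sensitivity={self.sensitivity:.3f} specificity={self.specificity:.3f}"
        )
        return "\n".join(lines)


def _control_peptides(control: ControlRecord, min_peptide_len: int) -> list[str]:
    seqs = control.sequence
    if not isinstance(seqs, list):
        seqs = None  # placeholder; read below with sniffing
        records = seqio.read_fasta(control.sequence, alphabet=_sniff(control))
    else:
        records = seqs
    peptides = []
    for rec in records:
        if rec.alphabet == seqio.DNA:
            for frame in seqio.six_frame_translate(rec, min_peptide_len=min_peptide_len):
                peptides.append(frame.peptide)
        else:
            peptides.append(rec.residues.replace("*", ""))
    return peptides


def _sniff(control: ControlRecord) -> str:
    if control.alphabet is not None:
        return control.alphabet
    with open(control.sequence) as fh:
        for line in fh:
            if line.startswith(">") or not line.strip():
                continue
            chars = set(line.strip().upper())
            return seqio.DNA if chars <= set("ACGTN") else seqio.PROTEIN
    return seqio.DNA


def _best_evalue(model: ProfileHMM, peptides: list[str], config: SearchConfig) -> float:
    if not peptides:
        return float("inf")
    scores = _batch_scores(model, peptides, config.score_kind)
    Z = config.Z if config.Z is not None else len(peptides)
    return min(evalue_of(float(s), model.calibration, Z) for s in scores)


def validate(
    model: ProfileHMM,
    controls: list[ControlRecord],
    search_config: SearchConfig | None = None,
) -> ValidationReport:
    """Screen every control and assemble the confusion-matrix report.

    Controls whose sequences cannot be read are excluded from the counts
    but flagged in ``report.errors``, never silently dropped.
    """
    config = search_config or SearchConfig()
    positives = [c for c in controls if c.is_positive]
    negatives = [c for c in controls if not c.is_positive]
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative control")
    rows, errors = [], []
    for control in controls:
        try:
            peptides = _control_peptides(control, config.min_peptide_len)
            best = _best_evalue(model, peptides, config)
        except OSError as exc:
            errors.append(f"{control.strain_label}: {exc}")
            continue
        rows.append(
            {
                "strain_label": control.strain_label,
                "expected_subclass": control.expected_subclass,
                "is_positive": control.is_positive,
                "detected": best <= config.evalue_cutoff,
                "best_evalue": best if np.isfinite(best) else np.nan,
            }
        )
    df = pd.DataFrame(
        rows, columns=["strain_label", "expected_subclass", "is_positive",
                       "detected", "best_evalue"],
    )
    tp = int(((df.is_positive) & (df.detected)).sum())
    fn = int(((df.is_positive) & (~df.detected)).sum())
    fp = int(((~df.is_positive) & (df.detected)).sum())
    tn = int(((~df.is_positive) & (~df.detected)).sum())
    return ValidationReport(
        per_control=df, true_positives=tp, false_negatives=fn,
        true_negatives=tn, false_positives=fp, errors=errors,
    )


def report_at_cutoff(report: ValidationReport, cutoff: float) -> ValidationReport:
    """Re-derive the confusion matrix at a different E-value cutoff."""
    df = report.per_control.copy()
    df["detected"] = df.best_evalue.fillna(np.inf) <= cutoff
    tp = int(((df.is_positive) & (df.detected)).sum())
    fn = int(((df.is_positive) & (~df.detected)).sum())
    fp = int(((~df.is_positive) & (df.detected)).sum())
    tn = int(((~df.is_positive) & (~df.detected)).sum())
    return ValidationReport(
        per_control=df, true_positives=tp, false_negatives=fn,
        true_negatives=tn, false_positives=fp, errors=list(report.errors),
    )


def subclass_discrimination(
    model: ProfileHMM,
    labeled_proteins: list[tuple[object, str]],
    search_config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Per-subclass detected/undetected counts for labelled proteins.

    The target family subclass (LanB) is expected detected; the other
    modification-enzyme subclasses are expected not detected.
    """
    config = search_config or SearchConfig()
    for _, subclass in labeled_proteins:
        if subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass label {subclass!r}")
    if not labeled_proteins:
        return pd.DataFrame(columns=["subclass", "n", "n_detected"]).set_index("subclass")
    peptides = [
        seq.residues if isinstance(seq, seqio.SequenceRecord) else str(seq)
        for seq, _ in labeled_proteins
    ]
    scores = _batch_scores(model, peptides, config.score_kind)
    Z = config.Z if config.Z is not None else len(peptides)
    rows = []
    for (seq, subclass), score in zip(labeled_proteins, scores):
        ev = evalue_of(float(score), model.calibration, Z)
        rows.append({"subclass": subclass, "detected": ev <= config.evalue_cutoff})
    df = pd.DataFrame(rows)
    table = df.groupby("subclass").agg(n=("detected", "size"), n_detected=("detected", "sum"))
    return table
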