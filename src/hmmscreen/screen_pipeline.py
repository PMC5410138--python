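"""Per-sample screening, hit densities by body site, and statistics.

A metagenome sample is screened by six-frame translating its contigs,
searching every peptide segment against the profile, and collapsing
hits whose nucleotide intervals overlap on the same contig (the same
gene found in two frames counts once, keeping the lowest E-value).
Densities are hits per assembled megabase; body sites follow the nine
Human Microbiome Project categories, with the eight non-stool sites
pooled as "oral" when comparing environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import seqio
from .search_engine import Hit, SearchConfig, search
from .profile_build import ProfileHMM

BODY_SITES = (
    "Attached Keratinized Gingiva",
    "Buccal Mucosa",
    "Palatine Tonsils",
    "Saliva",
    "Stool",
    "Subgingival Plaque",
    "Supragingival Plaque",
    "Throat",
    "Tongue Dorsum",
)
ORAL_SITES = tuple(s for s in BODY_SITES if s != "Stool")


class DegenerateDataError(ValueError):
    """All observations identical; no test statistic is defined."""


@dataclass
class SampleSummary:
    """Hit count, assembly size and hit density for one sample."""

    sample_id: str
    body_site: str
    n_hits: int
    assembly_mb: float

    def __post_init__(self) -> None:
        if self.assembly_mb <= 0:
            raise ValueError("assembly_mb must be positive")
        if self.n_hits < 0:
            raise ValueError("n_hits must be non-negative")

    @property
    def density(self) -> float:
        return self.n_hits / self.assembly_mb

    @property
    def has_hit(self) -> bool:
        return self.n_hits >= 1


@dataclass
class MethodOverlap:
    """Region counts of a 2- or 3-way hit-set comparison.

    region_counts maps a frozenset of method names to the number of
    distinct loci found by exactly that set of methods.
    """

    method_names: list[str]
    region_counts: dict[frozenset, int]

    def total_for(self, method: str) -> int:
        return sum(c for region, c in self.region_counts.items() if method in region)

    def as_series(self) -> pd.Series:
        labels = {}
        for r in sorted(self.region_counts, key=lambda r: (len(r), sorted(r))):
            labels["&".join(sorted(r))] = self.region_counts[r]
        return pd.Series(labels, dtype=int)


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def _intervals_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def dedup_hits(hits: list[Hit]) -> list[Hit]:
    """Collapse hits overlapping >= 1 bp on the same contig across frames.

    Greedy by ascending E-value, so each locus keeps its best hit.
    """
    kept: list[Hit] = []
    by_contig: dict[str, list[Hit]] = {}
    for hit in sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.target_id)):
        if hit.contig_id is None or hit.nt_start is None:
            kept.append(hit)
            continue
        clash = any(
            _intervals_overlap(hit.nt_start, hit.nt_end, k.nt_start, k.nt_end) >= 1
            for k in by_contig.get(hit.contig_id, [])
        )
        if not clash:
            kept.append(hit)
            by_contig.setdefault(hit.contig_id, []).append(hit)
    return kept


def screen_sample(
    model: ProfileHMM,
    contig_fasta,
    site: str,
    search_config: SearchConfig | None = None,
    sample_id: str | None = None,
) -> tuple[SampleSummary, list[Hit]]:
    """Six-frame translate, search and deduplicate one assembly."""
    search_config = search_config or SearchConfig()
    contigs = (
        contig_fasta
        if isinstance(contig_fasta, list)
        else seqio.read_fasta(contig_fasta, alphabet=seqio.DNA)
    )
    if not contigs:
        raise ValueError(f"empty assembly for sample {sample_id or contig_fasta}")
    sample_id = sample_id or str(contig_fasta)
    total_nt = sum(len(c) for c in contigs)
    frames = []
    for contig in contigs:
        frames.extend(
            seqio.six_frame_translate(contig, min_peptide_len=search_config.min_peptide_len)
        )
    hits = dedup_hits(search(model, frames, search_config))
    for hit in hits:
        hit.sample_id = sample_id
    summary = SampleSummary(
        sample_id=sample_id,
        body_site=site,
        n_hits=len(hits),
        assembly_mb=total_nt / 1e6,
    )
    return summary, hits


def screen_genomes(
    model: ProfileHMM,
    genome_fastas,
    search_config: SearchConfig | None = None,
) -> tuple[list[Hit], float]:
    """Screen a set of reference genomes; one aggregate hits/Mb density."""
    all_hits: list[Hit] = []
    total_mb = 0.0
    for i, fasta in enumerate(genome_fastas):
        summary, hits = screen_sample(
            model, fasta, site="genome", search_config=search_config,
            sample_id=f"genome{i:03d}" if isinstance(fasta, list) else str(fasta),
        )
        total_mb += summary.assembly_mb
        all_hits.extend(hits)
    return all_hits, len(all_hits) / total_mb


def density_table(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Per-site aggregation: n samples, total hits, mean density, % with hit."""
    if not summaries:
        raise ValueError("no sample summaries given")
    rows = []
    for s in summaries:
        site = s.body_site
        if site not in BODY_SITES:
            warnings.warn(f"unknown body site {site!r}; grouped under 'other'")
            site = "other"
        rows.append(
            {"body_site": site, "n_hits": s.n_hits, "density": s.density,
             "has_hit": s.has_hit}
        )
    df = pd.DataFrame(rows)
    table = df.groupby("body_site").agg(
        n_samples=("n_hits", "size"),
        total_hits=("n_hits", "sum"),
        mean_density=("density", "mean"),
        pct_with_hit=("has_hit", lambda x: 100.0 * x.mean()),
    )
    return table.sort_index()


def oral_stool_densities(summaries: list[SampleSummary]) -> tuple[list[float], list[float]]:
    """Pooled per-sample densities: the eight oral sites vs stool."""
    oral = [s.density for s in summaries if s.body_site in ORAL_SITES]
    stool = [s.density for s in summaries if s.body_site == "Stool"]
    return oral, stool


def compare_densities(
    group_a, group_b, test: str = "wilcoxon_rank_sum",
    labels: tuple[str, str] = ("A", "B"),
) -> StatResult:
    """Two-sided Wilcoxon rank-sum or Welch's t-test on two density groups.

    The Wilcoxon path is exact (full enumeration, via the Mann-Whitney
    null distribution) when the combined size is <= 10 and there are no
    ties; otherwise it uses the normal approximation with midranks and
    continuity correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateDataError("all observations identical in both groups")
    if test == "wilcoxon_rank_sum":
        combined = np.concatenate([a, b])
        tie_free = len(np.unique(combined)) == len(combined)
        method = "exact" if (len(combined) <= 10 and tie_free) else "asymptotic"
        res = _scipy_stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
        statistic = float(res.statistic)  # Mann-Whitney U of group A
        p = float(res.pvalue)
    elif test == "welch_t":
        res = _scipy_stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatResult(
        test_name=test, statistic=statistic, p_value=min(p, 1.0),
        group_labels=labels, group_sizes=(len(a), len(b)),
    )


def _collapse_within_method(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Merge duplicate loci within one method (>= 50%-of-shorter overlap)."""
    keep = []
    for (_, _), group in df.groupby(["sample_id", "contig_id"], dropna=False):
        rows = group.sort_values(["nt_start", "nt_end"]).to_dict("records")
        merged: list[dict] = []
        for row in rows:
            dup = False
            for m in merged:
                ov = _intervals_overlap(row["nt_start"], row["nt_end"], m["nt_start"], m["nt_end"])
                shorter = min(row["nt_end"] - row["nt_start"] + 1, m["nt_end"] - m["nt_start"] + 1)
                if ov >= 0.5 * shorter:
                    dup = True
                    break
            if dup:
                warnings.warn(f"duplicate locus within method {name!r} collapsed")
            else:
                merged.append(row)
        keep.extend(merged)
    return pd.DataFrame(keep, columns=df.columns)


def method_overlap(hit_tables: dict[str, pd.DataFrame]) -> MethodOverlap:
    """Partition loci by which subset of 2-3 methods found them.

    Tables need columns sample_id, contig_id, nt_start, nt_end.  Two
    hits from different methods are the same locus when their intervals
    on the same (sample, contig) overlap by at least 50% of the shorter.
    """
    names = list(hit_tables)
    if not 2 <= len(names) <= 3:
        raise ValueError("method_overlap compares 2 or 3 hit tables")
    nodes = []  # (method, sample, contig, start, end)
    for name in names:
        df = hit_tables[name]
        if len(df):
            df = _collapse_within_method(df, name)
        for _, row in df.iterrows():
            nodes.append(
                (name, row.get("sample_id"), row["contig_id"],
                 int(row["nt_start"]), int(row["nt_end"]))
            )
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (mi, si, ci, s_i, e_i) in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            mj, sj, cj, s_j, e_j = nodes[j]
            if mi == mj or si != sj or ci != cj:
                continue
            ov = _intervals_overlap(s_i, e_i, s_j, e_j)
            if ov >= 0.5 * min(e_i - s_i + 1, e_j - s_j + 1):
                parent[find(i)] = find(j)
    components: dict[int, set] = {}
    for i in range(len(nodes)):
        components.setdefault(find(i), set()).add(nodes[i][0])
    counts: dict[frozenset, int] = {}
    for methods in components.values():
        key = frozenset(methods)
        counts[key] = counts.get(key, 0) + 1
    return MethodOverlap(method_names=names, region_counts=counts)


# ---------------------------------------------------------------------------
# Tabular output (deterministic formatting for byte-identical reruns)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "model", "target", "sample_id", "contig", "frame",
    "nt_start", "nt_end", "ali_start", "ali_end", "bit_score", "evalue",
)


def hits_to_frame(hits: list[Hit]) -> pd.DataFrame:
    rows = [
        {
            "model": h.model_name, "target": h.target_id, "sample_id": h.sample_id,
            "contig": h.contig_id, "frame": h.frame,
            "nt_start": h.nt_start, "nt_end": h.nt_end,
            "ali_start": h.ali_start, "ali_end": h.ali_end,
            "bit_score": round(h.bit_score, 4), "evalue": f"{h.evalue:.4g}",
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits: list[Hit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def summaries_to_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "body_site": s.body_site,
                "n_hits": s.n_hits, "assembly_mb": round(s.assembly_mb, 6),
                "density": round(s.density, 6), "has_hit": s.has_hit,
            }
            for s in summaries
        ]
    )
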