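"""Regulatory screen: DEG filtering, candidate intersection, hub ranking,
and promoter PWM scanning with composite-element detection.

The gene-level half reproduces the screening procedure used to nominate
immunoregulatory transcription-factor targets: filter differentially
expressed genes by strict fold-change/p-value cut-offs, intersect them
with a TF-target list and an immune-annotation list, then rank the
members of a score-thresholded interaction network by degree to find
hubs.  The promoter-level half scans sequences with position weight
matrices at a relative-profile-score threshold (default 85%) and pairs
proximal hits of two factors into composite elements, the configuration
found for E2F1 and STAT3 on the IL6 promoter.

Coordinates are 0-based half-open internally; promoter positions can be
reported as negative offsets from the transcription start site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEGRecord",
    "CandidateSet",
    "HubRanking",
    "PWM",
    "MotifHit",
    "CompositeElement",
    "filter_degs",
    "intersect_candidates",
    "hub_rank",
    "relative_score",
    "scan_sequence",
    "find_composite_elements",
    "harmonize_symbols",
    "load_builtin_pwms",
    "read_deg_table",
    "read_gene_list",
    "read_edge_list",
    "hits_to_bed",
    "tss_offset",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# gene-level screen


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression call (signed linear fold change)."""

    gene: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.fold_change):
            raise ValueError(f"{self.gene}: fold change must be finite")
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"{self.gene}: p-value must lie in [0, 1]")


@dataclass
class CandidateSet:
    """Result of the three-way candidate intersection."""

    genes: set[str]
    n_tf_targets: int
    n_immune: int
    n_deg_pass: int
    n_candidates: int
    fraction_tf_in_immune: float


@dataclass
class HubRanking:
    """Degree ranking of a score-thresholded interaction network."""

    ranking: pd.DataFrame          # columns gene, degree; hub first
    n_nodes: int
    n_edges: int

    @property
    def hub(self) -> str | None:
        return None if self.ranking.empty else str(self.ranking.iloc[0]["gene"])


def harmonize_symbols(genes: Iterable[str]) -> set[str]:
    """Case-fold and strip gene symbols into one namespace."""
    return {str(g).strip().upper() for g in genes if str(g).strip()}


def _as_records(records) -> list[DEGRecord]:
    if isinstance(records, pd.DataFrame):
        return [DEGRecord(str(r.gene), float(r.fold_change), float(r.p_value))
                for r in records.itertuples(index=False)]
    return [r if isinstance(r, DEGRecord) else DEGRecord(*r) for r in records]


def filter_degs(records, p_cut: float = 0.05, fc_cut: float = 1.5,
                direction: str = "down") -> set[str]:
    """Genes passing strict DEG cut-offs: p < p_cut and |FC| > fc_cut.

    Both inequalities are strict, so boundary records (p == p_cut or
    |FC| == fc_cut) are excluded.  ``direction`` selects down- (FC < -cut),
    up- (FC > cut) or two-sided calls.  Duplicate symbols collapse to the
    most significant (lowest-p) record before filtering.
    """
    if not (0 < p_cut <= 1):
        raise ValueError("p_cut must lie in (0, 1]")
    if fc_cut < 1:
        raise ValueError("fc_cut is a fold change and must be >= 1")
    if direction not in ("down", "up", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    best: dict[str, DEGRecord] = {}
    for rec in _as_records(records):
        cur = best.get(rec.gene)
        if cur is None or rec.p_value < cur.p_value:
            best[rec.gene] = rec
    out = set()
    for rec in best.values():
        if rec.p_value >= p_cut:
            continue
        if direction == "down" and rec.fold_change < -fc_cut:
            out.add(rec.gene)
        elif direction == "up" and rec.fold_change > fc_cut:
            out.add(rec.gene)
        elif direction == "both" and abs(rec.fold_change) > fc_cut:
            out.add(rec.gene)
    return out


def intersect_candidates(tf_targets: set[str], immune_genes: set[str],
                         deg_pass: set[str]) -> CandidateSet:
    """Three-way intersection of TF targets, immune genes and DEGs.

    Symbol namespaces must already be harmonized (see
    :func:`harmonize_symbols`).  Also reports which fraction of the immune
    list carries a TF binding site.
    """
    if not immune_genes:
        raise ValueError("immune_genes is empty; fraction_tf_in_immune undefined")
    tf_targets, immune_genes, deg_pass = set(tf_targets), set(immune_genes), set(deg_pass)
    candidates = tf_targets & immune_genes & deg_pass
    return CandidateSet(
        genes=candidates,
        n_tf_targets=len(tf_targets),
        n_immune=len(immune_genes),
        n_deg_pass=len(deg_pass),
        n_candidates=len(candidates),
        fraction_tf_in_immune=len(tf_targets & immune_genes) / len(immune_genes),
    )


def hub_rank(edges, score_cut: float = 0.4, genes: set[str] | None = None) -> HubRanking:
    """Rank genes by degree in the score-thresholded interaction network.

    Edges with weight strictly above ``score_cut`` between genes of the
    (optional) restriction set are kept; degree ties break
    lexicographically.  Self-loops are rejected.
    """
    import networkx as nx

    if isinstance(edges, pd.DataFrame):
        edges = list(edges[["gene_a", "gene_b", "score"]].itertuples(index=False))
    G = nx.Graph()
    n_seen = 0
    for a, b, w in edges:
        a, b, w = str(a), str(b), float(w)
        if a == b:
            raise ValueError(f"self-loop on {a!r} rejected")
        if not (0 <= w <= 1):
            raise ValueError(f"edge weight {w} outside [0, 1]")
        if w <= score_cut:
            continue
        if genes is not None and (a not in genes or b not in genes):
            continue
        G.add_edge(a, b)
    rows = sorted(((g, d) for g, d in G.degree()), key=lambda t: (-t[1], t[0]))
    ranking = pd.DataFrame(rows, columns=["gene", "degree"])
    return HubRanking(ranking=ranking, n_nodes=G.number_of_nodes(),
                      n_edges=G.number_of_edges())


# ---------------------------------------------------------------------------
# promoter-level screen


@dataclass
class PWM:
    """Log-odds position weight matrix over A/C/G/T.

    Built from a position frequency matrix with a pseudocount (default
    0.8, split by the background) and a uniform 0.25 background.  The
    relative score of a window rescales its summed log-odds linearly
    between the matrix's minimum and maximum attainable scores, onto
    [0, 1].
    """

    matrix: np.ndarray             # (4, length) log-odds, rows in A,C,G,T order
    source_id: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have shape (4, length)")
        if self.length < 4:
            raise ValueError("PWM length must be >= 4")
        if not self.max_score > self.min_score:
            raise ValueError("degenerate PWM: max_score must exceed min_score")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    @property
    def anticonsensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmin(axis=0))

    @classmethod
    def from_counts(cls, counts, source_id: str = "pwm", pseudocount: float = 0.8,
                    background: float = 0.25) -> "PWM":
        """PFM (counts) -> log-odds with pseudocount and uniform background."""
        if isinstance(counts, Mapping):
            counts = np.array([counts[b] for b in _BASES], dtype=float)
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, length) in A,C,G,T order")
        if counts.size == 0:
            raise ValueError("empty count matrix")
        totals = counts.sum(axis=0)
        probs = (counts + pseudocount * background) / (totals + pseudocount)
        return cls(matrix=np.log2(probs / background), source_id=source_id)

    @classmethod
    def from_jaspar(cls, path: str, pseudocount: float = 0.8) -> "PWM":
        """Read the first matrix of a JASPAR flat file."""
        from Bio import motifs

        with open(path) as fh:
            motif = motifs.read(fh, "jaspar")
        counts = np.array([motif.counts[b] for b in _BASES], dtype=float)
        return cls.from_counts(counts, source_id=motif.matrix_id or motif.name,
                               pseudocount=pseudocount)

    def _encoded(self, window: str) -> np.ndarray:
        try:
            return np.array([4 if b == "N" else _BASE_INDEX[b]
                             for b in window.upper()], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"invalid symbol {e.args[0]!r} in window") from None


@dataclass(frozen=True)
class MotifHit:
    """One PWM match on a sequence (start in plus-strand 0-based coords)."""

    sequence_id: str
    start: int
    strand: str
    raw_score: float
    relative_score: float
    factor: str
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def center(self) -> float:
        return self.start + (self.width - 1) / 2


@dataclass(frozen=True)
class CompositeElement:
    """A proximal pair of hits for two factors on one promoter."""

    e2f1_hit: MotifHit
    stat3_hit: MotifHit
    center_gap: float              # stat3 center - e2f1 center, bp (signed)
    orientation: str               # e2f1_upstream | stat3_upstream | overlapping


def relative_score(pwm: PWM, window: str) -> float:
    """Relative profile score of one window: (raw - min) / (max - min).

    The window must match the PWM length; ``N`` scores as the
    per-position minimum.  1.0 is attained exactly by the consensus, 0.0
    by the per-position-worst word.
    """
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    idx = pwm._encoded(window)
    per_pos_min = pwm.matrix.min(axis=0)
    ext = np.vstack([pwm.matrix, per_pos_min])
    raw = float(ext[idx, np.arange(pwm.length)].sum())
    return (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_sequence(seq: str, pwm: PWM, threshold: float = 0.85,
                  both_strands: bool = True, factor: str = "TF",
                  sequence_id: str = "seq") -> list[MotifHit]:
    """All windows scoring at least ``threshold`` relative, sorted by start.

    With ``both_strands`` the reverse complement of each window is scored
    too; minus-strand hits report the window's plus-strand start.
    Overlapping hits are all reported.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    seq = seq.upper()
    w = pwm.length
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} shorter than motif ({w})")
    per_pos_min = pwm.matrix.min(axis=0)
    ext = np.vstack([pwm.matrix, per_pos_min])
    idx = pwm._encoded(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    cols = np.arange(w)
    raw_plus = ext[windows, cols].sum(axis=1)
    span = pwm.max_score - pwm.min_score
    rel_plus = (raw_plus - pwm.min_score) / span
    hits = []
    for i in np.nonzero(rel_plus >= threshold)[0]:
        hits.append(MotifHit(sequence_id, int(i), "+", float(raw_plus[i]),
                             float(rel_plus[i]), factor, w))
    if both_strands:
        # score the reverse complement of each plus-strand window: equivalent
        # to scanning with the reverse-complemented matrix (complement rows
        # A<->T / C<->G, reverse columns)
        rc_matrix = pwm.matrix[[3, 2, 1, 0]][:, ::-1]
        rc_full = np.vstack([rc_matrix, rc_matrix.min(axis=0)])
        raw_minus = rc_full[windows, cols].sum(axis=1)
        rel_minus = (raw_minus - pwm.min_score) / span
        for i in np.nonzero(rel_minus >= threshold)[0]:
            hits.append(MotifHit(sequence_id, int(i), "-", float(raw_minus[i]),
                                 float(rel_minus[i]), factor, w))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_composite_elements(hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit],
                            max_gap: float = 50.0) -> list[CompositeElement]:
    """All cross-factor hit pairs with motif-center distance <= max_gap.

    Both hit lists must come from one sequence.  Pairs are sorted by
    absolute gap, then position; each pair is reported once.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ids = {h.sequence_id for h in hits_a} | {h.sequence_id for h in hits_b}
    if len(ids) > 1:
        raise ValueError(f"hits come from multiple sequences: {sorted(ids)}")
    out = []
    for ha in hits_a:
        for hb in hits_b:
            gap = hb.center - ha.center
            if abs(gap) <= max_gap:
                if gap > 0:
                    orientation = "e2f1_upstream"
                elif gap < 0:
                    orientation = "stat3_upstream"
                else:
                    orientation = "overlapping"
                out.append(CompositeElement(ha, hb, float(gap), orientation))
    out.sort(key=lambda c: (abs(c.center_gap), min(c.e2f1_hit.start, c.stat3_hit.start)))
    return out


# ---------------------------------------------------------------------------
# IO helpers


def load_builtin_pwms(pseudocount: float = 0.8) -> dict[str, PWM]:
    """The shipped synthetic E2F1/STAT3 toy matrices (JASPAR flat format)."""
    from importlib import resources

    out = {}
    for factor in ("E2F1", "STAT3"):
        path = resources.files("il6loop") / "data" / "motifs" / f"{factor}_synthetic.jaspar"
        with resources.as_file(path) as p:
            out[factor] = PWM.from_jaspar(str(p), pseudocount=pseudocount)
    return out


def read_deg_table(path: str) -> list[DEGRecord]:
    """TSV with columns gene, fold_change, p_value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "fold_change", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return _as_records(df)


def read_gene_list(path: str) -> set[str]:
    """One symbol per line; harmonized."""
    with open(path) as fh:
        return harmonize_symbols(line for line in fh)


def read_edge_list(path: str) -> pd.DataFrame:
    """TSV with columns gene_a, gene_b, score."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    return df


def tss_offset(hit: MotifHit, seq_length: int) -> int:
    """Promoter position of a hit as a negative offset from the TSS.

    Assumes the scanned sequence is a promoter ending at the TSS (the
    base immediately 5' of it), so a hit starting ``start`` covers
    positions -(L - start) .. -(L - end + 1).
    """
    return -(seq_length - hit.start)


def hits_to_bed(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """BED-like table: sequence, start, end, factor, strand, relative_score."""
    return pd.DataFrame(
        [{"sequence": h.sequence_id, "start": h.start, "end": h.end,
          "factor": h.factor, "strand": h.strand,
          "relative_score": round(h.relative_score, 6)} for h in hits]
    )
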