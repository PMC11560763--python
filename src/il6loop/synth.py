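"""Seeded synthetic-data generators with recorded ground truth.

Every generator is a pure function of its arguments including the seed;
one global seed fans out to fixed per-generator substreams, so adding a
generator never shifts existing outputs.  Ground truths are computed by
independent construction-time logic, never by calling the module whose
behaviour the fixture is meant to test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import ConditionSpec, run_panel, standard_panel
from .screen import PWM

__all__ = [
    "ObservationTable",
    "RegulatoryFixture",
    "PromoterFixture",
    "Plant",
    "gen_cytokine_observations",
    "gen_regulatory_fixture",
    "gen_promoter_set",
]

# fixed substream ids: cytokine | regulatory | promoter
_STREAMS = {"cytokine": 11, "regulatory": 12, "promoter": 13}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# cytokine observations


@dataclass
class ObservationTable:
    """Replicate analyte measurements per condition.

    ``metadata`` (seed, noise model, true underlying means) is present
    exactly when the table is synthetic; tables loaded from disk carry
    none.
    """

    frame: pd.DataFrame            # condition, analyte, replicate, value
    metadata: dict | None = None

    def values_for(self, condition: str) -> np.ndarray:
        sel = self.frame[self.frame["condition"] == condition]
        return sel["value"].to_numpy()

    def to_tsv(self, path: str, metadata_path: str | None = None) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
        if metadata_path and self.metadata is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str) -> "ObservationTable":
        frame = pd.read_csv(path, sep="\t")
        missing = {"condition", "analyte", "replicate", "value"} - set(frame.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        return cls(frame=frame, metadata=None)


def gen_cytokine_observations(conditions: list[ConditionSpec] | None = None,
                              config: dict | None = None, cv: float = 0.1,
                              n_rep: int = 3, seed: int = 0) -> ObservationTable:
    """ELISA-like replicate IL-6 readouts for a condition panel.

    Each condition is simulated deterministically; replicates then draw
    multiplicative lognormal noise with the requested coefficient of
    variation (mean-preserving, so the expected value of each replicate
    equals the deterministic readout; cv=0 reproduces it exactly).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if conditions is None:
        conditions = standard_panel()
    panel = run_panel(conditions, config)
    rng = _rng(seed, "cytokine")
    sigma = math.sqrt(math.log1p(cv ** 2))
    rows = []
    true_means = {}
    for name, mu in zip(panel.table["condition"], panel.table["IL6_readout"]):
        true_means[name] = float(mu)
        z = rng.standard_normal(n_rep)
        vals = mu * np.exp(sigma * z - sigma ** 2 / 2)
        for r, v in enumerate(vals, start=1):
            rows.append({"condition": name, "analyte": "IL6",
                         "replicate": r, "value": float(v)})
    meta = {"seed": int(seed), "cv": float(cv), "n_rep": int(n_rep),
            "noise": "lognormal-multiplicative", "true_means": true_means}
    return ObservationTable(frame=pd.DataFrame(rows), metadata=meta)


# ---------------------------------------------------------------------------
# regulatory fixture


@dataclass
class RegulatoryFixture:
    """Gene tables with the statistical structure of the TF screen."""

    tf_targets: set[str]
    immune_genes: set[str]
    deg_table: pd.DataFrame        # gene, fold_change, p_value
    truth_candidates: set[str]
    params: dict

    def to_files(self, deg_path: str, tf_path: str, immune_path: str,
                 truth_path: str | None = None) -> None:
        self.deg_table.to_csv(deg_path, sep="\t", index=False)
        for path, genes in ((tf_path, self.tf_targets), (immune_path, self.immune_genes)):
            with open(path, "w") as fh:
                fh.write("\n".join(sorted(genes)) + "\n")
        if truth_path:
            with open(truth_path, "w") as fh:
                json.dump({"truth_candidates": sorted(self.truth_candidates),
                           "params": self.params}, fh, indent=2)


def gen_regulatory_fixture(n_genes: int = 200, p_tf: float = 0.6,
                           p_immune: float = 0.4, n_true_down: int = 25,
                           fc_range: tuple[float, float] = (1.6, 5.0),
                           seed: int = 0, p_cut: float = 0.05,
                           fc_cut: float = 1.5) -> RegulatoryFixture:
    """A gene universe with planted down-regulated TF/immune candidates.

    Truly-down genes draw fold changes uniformly in -[fc_range] and
    p-values in (0, 0.01); null genes draw fold changes in (-1.2, 1.2)
    and p-values uniform in (0, 1), so nulls can never pass a 1.5-fold
    cut.  ``truth_candidates`` is computed here by direct set logic with
    the stated cuts, independent of the screening module.
    """
    if not (0 <= n_true_down <= n_genes):
        raise ValueError("n_true_down must lie in [0, n_genes]")
    if not (0 < p_tf <= 1 and 0 < p_immune <= 1):
        raise ValueError("membership proportions must lie in (0, 1]")
    if not (1 < fc_range[0] < fc_range[1]):
        raise ValueError("fc_range must satisfy 1 < lo < hi")
    rng = _rng(seed, "regulatory")
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    tf = {g for g in genes if rng.random() < p_tf}
    immune = {g for g in genes if rng.random() < p_immune}
    down = set(rng.choice(genes, size=n_true_down, replace=False)) if n_true_down else set()
    rows = []
    for g in genes:
        if g in down:
            fc = -rng.uniform(*fc_range)
            p = rng.uniform(0, 0.01)
        else:
            fc = rng.uniform(-1.2, 1.2)
            p = rng.uniform(0, 1)
        rows.append({"gene": g, "fold_change": fc, "p_value": p})
    deg = pd.DataFrame(rows)
    # ground truth by direct construction-time logic (strict cuts)
    passing = {r["gene"] for r in rows
               if r["p_value"] < p_cut and r["fold_change"] < -fc_cut}
    truth = passing & tf & immune
    return RegulatoryFixture(
        tf_targets=tf, immune_genes=immune, deg_table=deg, truth_candidates=truth,
        params={"n_genes": n_genes, "p_tf": p_tf, "p_immune": p_immune,
                "n_true_down": n_true_down, "fc_range": list(fc_range),
                "seed": int(seed), "p_cut": p_cut, "fc_cut": fc_cut})


# ---------------------------------------------------------------------------
# promoter fixture


@dataclass(frozen=True)
class Plant:
    """Record of one motif insertion."""

    sequence_id: str
    factor: str
    offset: int                    # 0-based plus-strand start
    strand: str
    kind: str                      # exact | mutated | composite


@dataclass
class PromoterFixture:
    """Random promoter-like sequences with planted TF motifs."""

    sequences: dict[str, str]      # id -> sequence
    plants: list[Plant]
    gc: float
    seed: int

    def to_fasta(self, path: str, plants_path: str | None = None) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=name, description="synthetic promoter")
                   for name, s in self.sequences.items()]
        seqio_write(records, path, "fasta")
        if plants_path:
            with open(plants_path, "w") as fh:
                json.dump([p.__dict__ for p in self.plants], fh, indent=2)


def _mutate(word: str, n: int, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = list(word)
    for pos in rng.choice(len(word), size=n, replace=False):
        alternatives = [b for b in bases if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def gen_promoter_set(n_seq: int = 10, length: int = 500,
                     pwms: dict[str, PWM] | None = None,
                     n_plants: dict[str, int] | None = None,
                     n_composite: int = 1, composite_gap: int = 13,
                     mutate: int = 0, gc: float = 0.41,
                     seed: int = 0) -> PromoterFixture:
    """Background promoters with planted (possibly mutated) motifs.

    Per sequence: ``n_plants[factor]`` single consensus plants per factor
    plus ``n_composite`` composite E2F1-STAT3 plants at the stated centre
    gap (the IL6-promoter-like geometry defaults to 13 bp).  ``mutate``
    positions of each single plant are mutated away from consensus.
    Plants never overlap; all are recorded.
    """
    if pwms is None:
        from .screen import load_builtin_pwms
        pwms = load_builtin_pwms()
    if n_plants is None:
        n_plants = {f: 1 for f in pwms}
    max_w = max(p.length for p in pwms.values())
    if length <= max_w + composite_gap + max_w:
        raise ValueError("sequence length too short for the requested plants")
    rng = _rng(seed, "promoter")
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    plants: list[Plant] = []
    for s in range(n_seq):
        name = f"promoter_{s + 1:03d}"
        seq = list("".join(rng.choice(bases, size=length, p=p_base)))
        occupied: list[tuple[int, int]] = []

        def place(width: int, tries: int = 200) -> int:
            for _ in range(tries):
                off = int(rng.integers(0, length - width + 1))
                if all(off + width <= a or off >= b for a, b in occupied):
                    occupied.append((off, off + width))
                    return off
            raise ValueError("cannot place requested plants without overlap")

        for _ in range(n_composite):
            e_pwm, s_pwm = pwms["E2F1"], pwms["STAT3"]
            pair_w = int(round(composite_gap + (e_pwm.length - 1) / 2
                               + (s_pwm.length - 1) / 2)) + 1
            width = max(pair_w, e_pwm.length)
            off = place(width)
            e_off = off
            s_center = e_off + (e_pwm.length - 1) / 2 + composite_gap
            s_off = int(round(s_center - (s_pwm.length - 1) / 2))
            if s_off < e_off + e_pwm.length:
                raise ValueError("composite_gap too small: the two motifs overlap")
            seq[e_off:e_off + e_pwm.length] = e_pwm.consensus
            seq[s_off:s_off + s_pwm.length] = s_pwm.consensus
            plants.append(Plant(name, "E2F1", e_off, "+", "composite"))
            plants.append(Plant(name, "STAT3", s_off, "+", "composite"))
        for factor, count in n_plants.items():
            pwm = pwms[factor]
            for _ in range(count):
                off = place(pwm.length)
                word = pwm.consensus
                kind = "exact"
                if mutate:
                    word = _mutate(word, mutate, rng)
                    kind = "mutated"
                seq[off:off + pwm.length] = word
                plants.append(Plant(name, factor, off, "+", kind))
        sequences[name] = "".join(seq)
    return PromoterFixture(sequences=sequences, plants=plants, gc=gc, seed=int(seed))
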