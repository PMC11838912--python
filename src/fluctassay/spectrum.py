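"""Mutational-spectrum tallies and parallelism probabilities.

Tools for summarising mutation spectra observed across replicate evolved
populations (counts per site and per mutation class) and for the simple
null-model arithmetic behind parallelism arguments: if two sites mutate at
equal rate and confer equal fitness, the chance that all n independent hits
land on one of them is 0.5^n; the k-of-n generalisation is an exact
binomial tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "MUTATION_COLUMNS",
    "MutationRecord",
    "SpectrumTally",
    "tally_spectrum",
    "prob_all_one_outcome",
    "binomial_tail",
    "format_scientific",
    "example_cc_spectrum",
    "example_q189w_spectrum",
]

MUTATION_COLUMNS = [
    "population_id",
    "gene_position",
    "ref_base",
    "alt_base",
    "mutation_class",
    "effect",
]

_CLASSES = ("point", "insertion", "deletion")


@dataclass
class MutationRecord:
    """One mutation observed in one evolved population.

    ``gene_position`` is 1-based on the coding strand of the gene; the codon
    index is ``ceil(position / 3)``.
    """

    population_id: str
    gene_position: int
    ref_base: str
    alt_base: str
    mutation_class: str = "point"
    effect: str = ""

    def validate(self) -> None:
        if self.gene_position < 1:
            raise ValueError("gene_position must be >= 1 (1-based)")
        if self.mutation_class not in _CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.mutation_class == "point" and self.ref_base == self.alt_base:
            raise ValueError("point mutation must change the base")

    @property
    def codon(self) -> int:
        return math.ceil(self.gene_position / 3)

    @property
    def label(self) -> str:
        return f"{self.ref_base}{self.gene_position}{self.alt_base}"


@dataclass
class SpectrumTally:
    """Counts of a mutation spectrum across populations."""

    site_counts: pd.Series  # indexed by (gene_position, ref_base, alt_base)
    class_counts: pd.Series  # indexed by mutation class
    n_records: int
    n_populations: int

    def count(self, label: str) -> int:
        """Count of a point mutation given as e.g. ``"C565T"``."""
        ref, pos, alt = label[0], int(label[1:-1]), label[-1]
        try:
            return int(self.site_counts.loc[(pos, ref, alt)])
        except KeyError:
            return 0


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in MUTATION_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return records
    for r in records:
        r.validate()
    return pd.DataFrame(
        [
            {
                "population_id": r.population_id,
                "gene_position": r.gene_position,
                "ref_base": r.ref_base,
                "alt_base": r.alt_base,
                "mutation_class": r.mutation_class,
                "effect": r.effect,
            }
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )


def tally_spectrum(records) -> SpectrumTally:
    """Tally a mutation spectrum per site and per mutation class.

    ``records`` is a list of :class:`MutationRecord` or a DataFrame in the
    mutation-record schema. Empty input yields empty tallies.
    """
    frame = _records_to_frame(records)
    if frame.empty:
        return SpectrumTally(
            site_counts=pd.Series(dtype=int),
            class_counts=pd.Series(dtype=int),
            n_records=0,
            n_populations=0,
        )
    site = frame.groupby(["gene_position", "ref_base", "alt_base"]).size()
    cls = frame.groupby("mutation_class").size()
    return SpectrumTally(
        site_counts=site,
        class_counts=cls,
        n_records=int(len(frame)),
        n_populations=int(frame["population_id"].nunique()),
    )


def prob_all_one_outcome(n: int, p: float) -> float:
    """Probability p^n that all n independent events take one outcome.

    Computed in log space so that values like 0.5^137 ~ 1e-42 keep full
    relative precision.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    return math.exp(n * math.log(p))


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    Summed in log space (logsumexp over log pmf terms) for stability at
    extreme tails.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if k == 0:
        return 1.0
    ks = np.arange(k, n + 1)
    logs = binom.logpmf(ks, n, p)
    logs = logs[np.isfinite(logs)]
    if logs.size == 0:
        return 0.0
    return float(math.exp(logsumexp(logs)))


def format_scientific(x: float, sig: int = 2) -> str:
    """Format a number in scientific notation at ``sig`` significant figures.

    ``5.66e-42`` at 2 significant figures renders as ``"5.7e-42"``.
    """
    if x == 0:
        return "0"
    return f"{x:.{sig - 1}e}"


def example_cc_spectrum() -> pd.DataFrame:
    """Spectrum of nlpD mutations across 139 cell-chaining populations.

    The canonical wild-type-derived spectrum: 137 populations with the
    C565T point mutation (CAG -> TAG, Q189*), one with G539A (G180D), and
    one with a frameshift insertion in the homopolymeric tract at base
    pairs 705-708 (Q237fs).
    """
    rows = [
        {
            "population_id": f"pop{i + 1:03d}",
            "gene_position": 565,
            "ref_base": "C",
            "alt_base": "T",
            "mutation_class": "point",
            "effect": "Q189*",
        }
        for i in range(137)
    ]
    rows.append(
        {
            "population_id": "pop138",
            "gene_position": 539,
            "ref_base": "G",
            "alt_base": "A",
            "mutation_class": "point",
            "effect": "G180D",
        }
    )
    rows.append(
        {
            "population_id": "pop139",
            "gene_position": 705,
            "ref_base": "-",
            "alt_base": "+1",
            "mutation_class": "insertion",
            "effect": "Q237fs",
        }
    )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def example_q189w_spectrum(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the Q189W-derived spectrum (37 populations).

    Eight populations carry the reverting G566A mutation (TGG -> TAG at
    codon 189); the identities of the remaining 29 mutations are known only
    to be scattered across the reading frame, so this builder fills them
    with synthetic scattered point and deletion records — the 8/37 tally is
    real, the other 29 positions are invented placeholders.
    """
    rng = np.random.default_rng(seed)
    rows = [
        {
            "population_id": f"qpop{i + 1:03d}",
            "gene_position": 566,
            "ref_base": "G",
            "alt_base": "A",
            "mutation_class": "point",
            "effect": "W189*",
        }
        for i in range(8)
    ]
    bases = "ACGT"
    for i in range(29):
        pos = int(rng.integers(1, 820))
        if rng.random() < 0.7:
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            rows.append(
                {
                    "population_id": f"qpop{i + 9:03d}",
                    "gene_position": pos,
                    "ref_base": str(ref),
                    "alt_base": str(alt),
                    "mutation_class": "point",
                    "effect": "",
                }
            )
        else:
            rows.append(
                {
                    "population_id": f"qpop{i + 9:03d}",
                    "gene_position": pos,
                    "ref_base": "-",
                    "alt_base": f"-{int(rng.integers(1, 30))}",
                    "mutation_class": "deletion",
                    "effect": "",
                }
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)
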