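"""Seeded synthetic two-library count data with planted differential
expression and planted GO enrichment.

The generator emulates the statistical structure of a two-condition
digital expression experiment: a fixed number of contigs with heavy-tailed
(log-normal) baseline abundances, two libraries of fixed total read depth
sampled multinomially against those abundances, a planted subset of
contigs whose second-library abundance is multiplied by a fold change
(> 1 for "up", < 1 for "down"), and per-contig GO annotations in which
chosen terms are enriched among the up-regulated contigs.  Multinomial
sampling conditions on the library totals, matching the assumption of the
conditional count test.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream in
a fixed draw order (baseline weights, DE assignment, fold magnitudes, term
prevalences, annotation matrix), so a config and seed fully determine the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acdge import DEResult, LibraryPair
from .tabio import AnnotationRecord, CountTable, TranscriptCounts

__all__ = ["SimConfig", "SimTruth", "RecoveryStats", "simulate",
           "evaluate_recovery"]


class SimConfigError(ValueError):
    """The simulation config is infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-library experiment.

    Defaults mirror a deep two-library run: 13,169 contigs over library
    totals 125,456 and 99,632 reads, log-normal baseline abundances with
    log-sd 1.8 (most contigs at 1-5 hits, a few in the hundreds), ~10% of
    contigs up- and ~8% down-regulated with median fold e^1 ≈ 2.7, and a
    sparse GO vocabulary of 200 terms averaging 0.87 terms per contig.
    """

    m: int = 13_169
    n_d: int = 125_456
    n_l: int = 99_632
    pi_up: float = 0.10
    pi_down: float = 0.08
    log_fold_mean: float = 1.0
    log_fold_sd: float = 0.5
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.8
    n_terms: int = 200
    terms_per_contig_mean: float = 0.87
    planted_terms: Sequence[tuple[str, float]] = field(default_factory=tuple)
    planted_base_prob: float = 0.1
    min_expected_de: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise SimConfigError("m must be >= 1")
        if self.n_d < 1 or self.n_l < 1:
            raise SimConfigError("library totals must be positive")
        if self.pi_up < 0 or self.pi_down < 0 or self.pi_up + self.pi_down > 1:
            raise SimConfigError("pi_up + pi_down must lie in [0, 1]")
        for p in (self.log_fold_sd, self.abundance_log_sd):
            if p <= 0:
                raise SimConfigError("scale parameters must be positive")
        if self.n_terms < 0 or self.terms_per_contig_mean < 0:
            raise SimConfigError("annotation parameters must be non-negative")
        for term, factor in self.planted_terms:
            if factor <= 0:
                raise SimConfigError(f"planted factor for {term} must be positive")
            if self.planted_base_prob * factor > 1.0:
                raise SimConfigError(
                    f"planted assignment probability {self.planted_base_prob * factor}"
                    f" > 1 for term {term}"
                )


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one contig."""

    contig_id: str
    baseline_weight: float
    fold: float
    is_de: str  # "up", "down" or "null"
    planted_terms_held: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class RecoveryStats:
    """How well a DE table recovers the planted truth."""

    power: float
    empirical_fdr: float
    direction_accuracy: float
    power_defined: bool
    fdr_defined: bool
    accuracy_defined: bool


def simulate(config: SimConfig) -> tuple[CountTable, list[AnnotationRecord], list[SimTruth]]:
    """Draw one synthetic experiment.

    Returns the count table (totals equal the configured library depths
    exactly), the annotation table (contigs with >= 1 GO term receive a
    synthetic accession), and the per-contig truth records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m

    # 1. baseline abundances (shared by both conditions)
    base = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, size=m)
    weights_d = base / base.sum()

    # 2. planted DE assignment
    n_up = int(round(config.pi_up * m))
    n_down = int(round(config.pi_down * m))
    eligible = np.arange(m)
    if config.min_expected_de > 0:
        eligible = eligible[weights_d * config.n_d >= config.min_expected_de]
    if n_up + n_down > eligible.size:
        raise SimConfigError(
            f"{n_up + n_down} DE contigs requested but only {eligible.size} "
            f"eligible (min expected hits {config.min_expected_de})"
        )
    chosen = rng.choice(eligible, size=n_up + n_down, replace=False)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]
    is_de = np.full(m, "null", dtype=object)
    is_de[up_idx] = "up"
    is_de[down_idx] = "down"

    # 3. fold changes (applied to the light-induced side)
    fold = np.ones(m)
    mags_up = np.abs(rng.normal(config.log_fold_mean, config.log_fold_sd, size=n_up))
    mags_down = np.abs(rng.normal(config.log_fold_mean, config.log_fold_sd, size=n_down))
    fold[up_idx] = np.exp(mags_up)
    fold[down_idx] = np.exp(-mags_down)

    weights_l = weights_d * fold
    weights_l = weights_l / weights_l.sum()

    hits_d = rng.multinomial(config.n_d, weights_d)
    hits_l = rng.multinomial(config.n_l, weights_l)

    # 4. GO vocabulary: heavy-tailed term prevalences scaled to the target
    #    annotation density, planted terms at a fixed common prevalence
    planted_names = [t for t, _ in config.planted_terms]
    decoy_names = [f"GO:{i:07d}" for i in range(1, config.n_terms + 1)
                   if f"GO:{i:07d}" not in set(planted_names)]
    terms = planted_names + decoy_names
    n_planted = len(planted_names)
    if decoy_names:
        raw = rng.lognormal(0.0, 1.5, size=len(decoy_names))
        decoy_prev = raw / raw.sum() * config.terms_per_contig_mean
        decoy_prev = np.clip(decoy_prev, 0.0, 0.5)
    else:
        decoy_prev = np.zeros(0)

    # 5. annotation matrix: independent Bernoulli per contig x term
    prev = np.empty((m, len(terms)))
    for j, (_, factor) in enumerate(config.planted_terms):
        p_term = np.full(m, config.planted_base_prob)
        p_term[is_de == "up"] *= factor
        prev[:, j] = p_term
    prev[:, n_planted:] = decoy_prev[None, :]
    has_term = rng.random(size=(m, len(terms))) < prev

    ids = [f"sim{i:05d}" for i in range(m)]
    records = [TranscriptCounts(ids[i], int(hits_d[i]), int(hits_l[i])) for i in range(m)]
    table = CountTable(records, LibraryPair(config.n_d, config.n_l))

    annotations: list[AnnotationRecord] = []
    truths: list[SimTruth] = []
    for i in range(m):
        held = frozenset(terms[j] for j in np.flatnonzero(has_term[i]))
        planted_held = frozenset(t for t in planted_names if t in held)
        if held:
            annotations.append(
                AnnotationRecord(ids[i], accession=f"SIM{i:05d}",
                                 description="synthetic ortholog", go_terms=held)
            )
        truths.append(SimTruth(ids[i], float(weights_d[i]), float(fold[i]),
                               str(is_de[i]), planted_held))
    return table, annotations, truths


def evaluate_recovery(de: list[DEResult], truth: list[SimTruth],
                      alpha: float = 0.05) -> RecoveryStats:
    """Empirical power, FDR and direction accuracy against planted truth.

    Power = significant true-DE / true-DE; empirical FDR = significant
    nulls / all significant; direction accuracy is over true-DE significant
    calls.  Undefined ratios (empty denominators) are returned as 0 with
    the matching ``*_defined`` flag set False.
    """
    t = {x.contig_id: x for x in truth}
    sig = [r for r in de if r.p_value < alpha]
    true_de = [x for x in truth if x.is_de != "null"]
    tp = [r for r in sig if t[r.contig_id].is_de != "null"]
    fp = [r for r in sig if t[r.contig_id].is_de == "null"]

    power_defined = len(true_de) > 0
    fdr_defined = len(sig) > 0
    accuracy_defined = len(tp) > 0
    return RecoveryStats(
        power=len(tp) / len(true_de) if power_defined else 0.0,
        empirical_fdr=len(fp) / len(sig) if fdr_defined else 0.0,
        direction_accuracy=(
            sum(1 for r in tp if r.direction == t[r.contig_id].is_de) / len(tp)
            if accuracy_defined else 0.0
        ),
        power_defined=power_defined,
        fdr_defined=fdr_defined,
        accuracy_defined=accuracy_defined,
    )


def write_truth_table(truths: list[SimTruth], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "contig_id": x.contig_id,
                "baseline_weight": f"{x.baseline_weight:.10e}",
                "fold": f"{x.fold:.8f}",
                "is_de": x.is_de,
                "planted_terms_held": "|".join(sorted(x.planted_terms_held)),
            }
            for x in truths
        ]
    ).to_csv(path, sep="\t", index=False)
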