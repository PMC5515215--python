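"""Seeded generators for every input the pipeline consumes.

Each generator emits both the simulated data and a ground-truth record,
so every downstream stage can be tested without external data:

* amplicon-like reads carrying the V6 primer site (degenerate positions
  concretised) followed by a planted 33-nt tag, with per-base error;
* spiked AHL decay time courses for the live / heat-inactivated / SWW
  conditions with adsorption loss and multiplicative lognormal noise;
* linear calibration tables with additive Gaussian baseline noise;
* taxa x time and AHL x time series with planted positive/negative
  Pearson correlations;
* isolate assay panels with planted producer / quencher / both /
  neither categories.

All generators are bit-reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._ahl import parse_acronym
from .kinetics import DecaySeries
from .community import CommunitySignalSeries
from .tags import IUPAC_CODES, TAG_LENGTH, V6_PRIMER, SequencingRead

_BASES = "ACGT"

#: Fixed flanking context placed before the primer site in simulated reads.
_FLANK = "TTGAGCTGACCAGTCAGGATCCTTAGCGAAAGCTAAGA"

#: Default calibration levels spanning the matrix-matched range (ug/l).
DEFAULT_CALIBRATION_LEVELS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)

ISOLATE_CATEGORIES = ("producer", "quencher", "both", "neither")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimPlan:
    """Plan for one taxon's reads: planted tag, depth, error rate, geometry."""

    taxon_id: str
    tag_sequence: str
    n_reads: int
    per_base_error_rate: float = 0.0
    read_length: int = 75
    primer_offset: int = 10

    def __post_init__(self) -> None:
        if len(self.tag_sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be exactly {TAG_LENGTH} nt")
        if set(self.tag_sequence) - set(_BASES):
            raise ValueError("tag must be over {A,C,G,T}")
        if not 0 <= self.per_base_error_rate < 0.5:
            raise ValueError("per-base error rate must be in [0, 0.5)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.primer_offset < 0:
            raise ValueError("primer_offset must be >= 0")


def _concretise_primer(rng: np.random.Generator, primer: str) -> str:
    out = []
    for code in primer:
        choices = sorted(IUPAC_CODES[code])
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0])
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in _BASES if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def gen_reads(
    plans: Sequence[ReadSimPlan],
    seed: int,
    primer: str = V6_PRIMER,
    min_reads: int = 2,
    max_type_fraction: float = 0.5,
) -> tuple[list[SequencingRead], pd.DataFrame]:
    """Simulate reads for each plan and a truth table of expected filter outcomes.

    Each read is: fixed flanking context (``primer_offset`` nt), the
    primer site with degenerate positions concretised uniformly at
    random, the (possibly error-mutated) planted tag, then random
    bases up to ``read_length``. The truth table applies the literal
    tag filters to the error-free occurrences of each planted tag, so
    it is consistent with the profiler by construction.
    """
    if not plans:
        raise ValueError("at least one plan required")
    rngs = _child_rngs(seed, len(plans))
    reads: list[SequencingRead] = []
    truth_rows = []
    read_no = 0
    for plan, rng in zip(plans, rngs):
        needed = plan.primer_offset + len(primer) + TAG_LENGTH
        if plan.read_length < needed:
            raise ValueError(
                f"{plan.taxon_id}: read_length {plan.read_length} < {needed} "
                "needed for an extractable tag"
            )
        flank = (_FLANK * (plan.primer_offset // len(_FLANK) + 1))[: plan.primer_offset]
        exact_types: dict[str, int] = {}
        for _ in range(plan.n_reads):
            site = _concretise_primer(rng, primer)
            tag = _mutate(rng, plan.tag_sequence, plan.per_base_error_rate)
            n_tail = plan.read_length - plan.primer_offset - len(primer) - TAG_LENGTH
            tail = "".join(_BASES[i] for i in rng.integers(4, size=n_tail))
            seq = flank + site + tag + tail
            read_no += 1
            reads.append(SequencingRead(
                read_id=f"sim_{plan.taxon_id}_{read_no}",
                sequence=seq,
                quality="?" * len(seq),  # constant Q30
            ))
            if tag == plan.tag_sequence:
                exact_types[seq] = exact_types.get(seq, 0) + 1
        total = sum(exact_types.values())
        max_frac = max(exact_types.values()) / total if total else 0.0
        reasons = []
        if total < min_reads:
            reasons.append(f"removed by >={min_reads}-read filter")
        if total and max_frac >= max_type_fraction:
            reasons.append("removed by single-read-type filter")
        truth_rows.append({
            "taxon_id": plan.taxon_id,
            "tag_sequence": plan.tag_sequence,
            "n_reads": plan.n_reads,
            "n_exact_tag_reads": total,
            "max_type_fraction": max_frac,
            "expected_kept": not reasons,
            "reason": "; ".join(reasons),
        })
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: Sequence[SequencingRead], path: str | Path) -> None:
    """Write reads as Sanger-quality FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "?" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Decay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySimPlan:
    """Plan for one AHL's spiked decay experiment (all three conditions).

    ``rate_constant`` is uM/h for order 0 and 1/h for order 1;
    ``adsorption_fraction`` is the instantaneous loss to biomass shared
    by the live and heat-inactivated conditions; ``abiotic_rate`` is the
    (default negligible) first-order loss in the SWW control.
    """

    ahl: str
    order: int
    rate_constant: float
    c0: float = 5.0  # uM, the spiking level
    adsorption_fraction: float = 0.0
    noise_cv: float = 0.0
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0)
    abiotic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        parse_acronym(self.ahl)  # validates the acronym
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.rate_constant <= 0 or self.c0 <= 0:
            raise ValueError("rate constant and c0 must be positive")
        if not 0 <= self.adsorption_fraction < 1:
            raise ValueError("adsorption fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if not self.timepoints:
            raise ValueError("timepoints must be non-empty")
        if self.timepoints[0] != 0 or any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be ascending and start at 0")


def _decay_factor(order: int, k: float, c0: float, t: np.ndarray) -> np.ndarray:
    if order == 0:
        return np.maximum(c0 - k * t, 0.0) / c0
    return np.exp(-k * t)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def gen_decay(plan: DecaySimPlan) -> dict[str, DecaySeries]:
    """Simulate the three decay conditions for one AHL.

    The SWW control decays only by the (negligible) abiotic rate; the
    heat-inactivated series shows the instantaneous adsorption drop but
    no enzymatic decay; the live series shows the adsorption drop plus
    the order-specified decay. Multiplicative lognormal noise with the
    stated CV (mean 1) is applied independently per condition.
    """
    t = np.asarray(plan.timepoints, dtype=float)
    rngs = _child_rngs(plan.seed, 3)
    abiotic = np.exp(-plan.abiotic_rate * t) if plan.abiotic_rate > 0 else np.ones_like(t)
    survive = 1.0 - plan.adsorption_fraction
    clean = {
        "sww_control": plan.c0 * abiotic,
        "heat_inactivated": plan.c0 * survive * abiotic,
        "live": plan.c0 * survive * abiotic
        * _decay_factor(plan.order, plan.rate_constant, plan.c0 * survive, t),
    }
    out = {}
    for (condition, conc), rng in zip(clean.items(), rngs):
        noisy = np.maximum(conc * _lognormal_noise(rng, plan.noise_cv, len(t)), 0.0)
        out[condition] = DecaySeries(
            ahl=plan.ahl, condition=condition, times=t, concentrations=noisy
        )
    return out


def decay_table(series_by_condition: dict[str, DecaySeries],
                replicate: int = 1) -> pd.DataFrame:
    """Long-format decay table (ahl, condition, replicate, time_h, concentration)."""
    rows = []
    for condition, s in series_by_condition.items():
        for t, c in zip(s.times, s.concentrations):
            rows.append({"ahl": s.ahl, "condition": condition,
                         "replicate": replicate, "time_h": float(t),
                         "concentration": float(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def gen_calibration(
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a calibration table: area = intercept + slope*level + N(0, noise_sd)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0.5) or np.any(levels > 200.0):
        raise ValueError("levels must lie within the 0.5-200 ug/l calibration range")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(levels)) if noise_sd > 0 else 0.0
    areas = intercept + slope * levels + noise
    return pd.DataFrame({"level_ugL": levels, "area": areas})


# ---------------------------------------------------------------------------
# Community series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySimPlan:
    """Plan for a taxa x time / AHL x time pair with planted correlations.

    ``planted_sign_matrix`` (n_taxa x n_ahls over {-1, 0, +1}) marks
    which taxon-AHL pairs carry a planted correlation of target
    magnitude ``effect_size``. ``noise_sd`` scales the independent
    taxon noise relative to the shared driver: at noise_sd=1 the
    population correlation equals exactly +/-effect_size; at noise_sd=0
    a planted pair is a deterministic affine copy (r = +/-1).
    """

    n_taxa: int
    n_timepoints: int
    n_ahls: int
    planted_sign_matrix: tuple[tuple[int, ...], ...]
    effect_size: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.planted_sign_matrix)
        if M.shape != (self.n_taxa, self.n_ahls):
            raise ValueError("sign matrix shape must be n_taxa x n_ahls")
        if not np.isin(M, (-1, 0, 1)).all():
            raise ValueError("sign matrix entries must be in {-1, 0, +1}")
        if not 0 < self.effect_size <= 1:
            raise ValueError("effect size must be in (0, 1]")
        if self.n_timepoints < 3:
            raise ValueError("at least 3 timepoints required for correlation")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def gen_community_series(
    plan: CommunitySimPlan,
) -> tuple[CommunitySignalSeries, pd.DataFrame]:
    """Simulate correlated taxa-abundance and AHL-concentration series.

    Each AHL follows a bounded unit-variance latent driver g (uniform on
    [-sqrt3, sqrt3]); its concentration is an increasing affine map of g
    (pmol/g scale). A taxon planted on AHL j with sign s follows
    rho*s*g_j + sqrt(1-rho^2)*noise_sd*eps and its abundance is an
    increasing affine map of that latent, so planted pairs have
    population Pearson correlation of the planted sign. Unplanted taxa
    are independent noise. Abundances stay nonnegative by construction
    of the bounded driver (residual normal noise is clipped at 0, a
    measure-zero event at default scales).
    """
    M = np.asarray(plan.planted_sign_matrix)
    rng = np.random.default_rng(plan.seed)
    sqrt3 = float(np.sqrt(3.0))
    g = rng.uniform(-sqrt3, sqrt3, size=(plan.n_ahls, plan.n_timepoints))
    rho = plan.effect_size
    taxa_latent = np.empty((plan.n_taxa, plan.n_timepoints))
    for i in range(plan.n_taxa):
        eps = rng.normal(0.0, 1.0, size=plan.n_timepoints)
        planted = np.flatnonzero(M[i])
        if len(planted) == 0:
            taxa_latent[i] = eps
            continue
        j = planted[0]
        if len(planted) > 1:
            # a taxon can only track one driver exactly; extra plants are ignored
            import logging
            logging.getLogger(__name__).info(
                "taxon %d planted on %d AHLs; using the first", i, len(planted)
            )
        taxa_latent[i] = rho * M[i, j] * g[j] + np.sqrt(1 - rho**2) * plan.noise_sd * eps

    timepoints = [f"week_{w}" for w in range(1, plan.n_timepoints + 1)]
    taxa_ab = np.maximum(0.02 * (1.0 + 0.25 * taxa_latent), 0.0)
    ahl_conc = 50.0 + 15.0 * g
    taxa_df = pd.DataFrame(taxa_ab, index=[f"tag_{i+1}" for i in range(plan.n_taxa)],
                           columns=timepoints)
    ahl_df = pd.DataFrame(ahl_conc, index=[f"ahl_{j+1}" for j in range(plan.n_ahls)],
                          columns=timepoints)
    truth = pd.DataFrame(M, index=taxa_df.index, columns=ahl_df.index)
    return CommunitySignalSeries(taxa_abundance=taxa_df, ahl_conc=ahl_df), truth


# ---------------------------------------------------------------------------
# Isolates
# ---------------------------------------------------------------------------

_PRODUCIBLE_AHLS = ("C6-HSL", "3OC6-HSL", "C8-HSL", "3OC8-HSL",
                    "C10-HSL", "3OC12-HSL", "C12-HSL")
_LONG_PRODUCIBLE = ("C10-HSL", "3OC12-HSL", "C12-HSL")


def gen_isolates(
    n: int,
    proportions: Sequence[float] = (0.052, 0.533, 0.048, 0.367),
    seed: int = 0,
    long_only_fraction: float = 0.77,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an isolate assay panel with planted QS/QQ categories.

    ``proportions`` are (producer-only, quencher-only, both, neither)
    and must sum to 1; category counts are multinomial. Among planted
    quenchers, ``long_only_fraction`` degrade only the long-chain
    3OC12-HSL while the rest also degrade a short/medium-chain AHL;
    every quencher degrades 3OC12-HSL. Producers activate at least one
    biosensor and carry >= 1 LC-MS/MS-confirmed AHL including a
    long-chain species. ``noise_sd`` adds Gaussian jitter to residual
    fractions (0 keeps the planted categories exactly recoverable).

    Returns the assay table and the planted category per isolate.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (4,):
        raise ValueError("proportions must have 4 entries "
                         "(producer-only, quencher-only, both, neither)")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    categories = rng.choice(["producer", "quencher", "both", "neither"],
                            size=n, p=proportions)
    rows = []
    for i, cat in enumerate(categories):
        is_producer = cat in ("producer", "both")
        is_quencher = cat in ("quencher", "both")
        produced: list[str] = []
        biosensors = {b: False for b in ("A136", "CV026", "JBA357")}
        if is_producer:
            produced = [str(rng.choice(_LONG_PRODUCIBLE))]
            n_extra = int(rng.integers(0, 3))
            extras = rng.choice(_PRODUCIBLE_AHLS, size=n_extra, replace=False)
            produced = sorted(set(produced) | set(map(str, extras)))
            for b in rng.choice(("A136", "CV026", "JBA357"),
                                size=int(rng.integers(1, 3)), replace=False):
                biosensors[str(b)] = True
        control = {ahl: float(rng.uniform(0.92, 1.02)) for ahl in
                   ("3OC6-HSL", "3OC8-HSL", "3OC12-HSL")}
        residual = dict(control)
        if is_quencher:
            residual["3OC12-HSL"] = control["3OC12-HSL"] * float(rng.uniform(0.02, 0.3))
            if rng.random() >= long_only_fraction:
                extra = str(rng.choice(("3OC6-HSL", "3OC8-HSL")))
                residual[extra] = control[extra] * float(rng.uniform(0.02, 0.3))
        else:
            # non-quenchers leave residuals near the control
            for ahl in residual:
                residual[ahl] = control[ahl] * float(rng.uniform(0.85, 1.05))
        if noise_sd > 0:
            for ahl in residual:
                residual[ahl] = max(residual[ahl] + float(rng.normal(0, noise_sd)), 0.0)
        rows.append({
            "isolate_id": f"R{i+1:03d}",
            "taxon": f"taxon_{i % 36 + 1}",
            "biosensor_A136": biosensors["A136"],
            "biosensor_CV026": biosensors["CV026"],
            "biosensor_JBA357": biosensors["JBA357"],
            "produced_ahls": ",".join(produced),
            "residual_3OC6": residual["3OC6-HSL"],
            "residual_3OC8": residual["3OC8-HSL"],
            "residual_3OC12": residual["3OC12-HSL"],
            "control_3OC6": control["3OC6-HSL"],
            "control_3OC8": control["3OC8-HSL"],
            "control_3OC12": control["3OC12-HSL"],
            "control_ph": float(rng.uniform(6.8, 7.25)),
        })
    table = pd.DataFrame(rows)
    truth = pd.Series(categories, index=table["isolate_id"], name="true_category")
    return table, truth
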