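"""Isolate QS/QQ phenotyping.

Each sludge isolate is screened for AHL production (activation of the
A. tumefaciens A136, C. violaceum CV026 or E. coli JBA357 biosensors,
with the produced AHL profile confirmed by LC-MS/MS) and for AHL
quenching (residual fraction of 3OC6-HSL, 3OC8-HSL and 3OC12-HSL after
a 2 h incubation, relative to a pH-matched sterile control). Isolates
are classified into producer / quencher / both / neither, and the
quencher set is summarised by its degradation spectrum (long-chain-only
vs long plus short/medium chains).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BIOSENSORS = ("A136", "CV026", "JBA357")
QUENCH_PANEL = ("3OC6-HSL", "3OC8-HSL", "3OC12-HSL")
LONG_CHAIN = "3OC12-HSL"
SHORT_MEDIUM = ("3OC6-HSL", "3OC8-HSL")
CATEGORIES = ("producer", "quencher", "both", "neither")

#: Overnight cultures must stay below this end-point pH for a valid
#: quench assay (alkaline conditions open the lactone ring abiotically).
MAX_CONTROL_PH = 7.3


class ControlQualityError(ValueError):
    """Raised when the pH-matched sterile control fails quality criteria."""


@dataclass
class IsolatePhenotype:
    """Per-isolate assay outcome and derived QS/QQ category."""

    isolate_id: str
    taxon: str = ""
    biosensor_positive: dict[str, bool] = field(default_factory=dict)
    produced_ahls: frozenset[str] = frozenset()
    residual_fraction: dict[str, float] = field(default_factory=dict)
    control_residual: dict[str, float] = field(default_factory=dict)
    quenched_ahls: frozenset[str] = frozenset()
    category: str = "neither"


def quenched_set(
    residual_fraction: Mapping[str, float],
    control_residual: Mapping[str, float],
    quench_threshold: float = 0.5,
) -> frozenset[str]:
    """AHLs whose residual, relative to the sterile control, is <= threshold."""
    if not 0 < quench_threshold < 1:
        raise ValueError("quench threshold must be in (0, 1)")
    quenched = set()
    for ahl, resid in residual_fraction.items():
        if ahl not in control_residual:
            logger.info("no control residual for %s; excluded from quench call", ahl)
            continue
        control = control_residual[ahl]
        if control <= 0:
            logger.info("control residual for %s is zero; excluded", ahl)
            continue
        if resid / control <= quench_threshold:
            quenched.add(ahl)
    return frozenset(quenched)


def classify_isolate(
    record: Mapping,
    quench_threshold: float = 0.5,
    max_control_ph: float = MAX_CONTROL_PH,
) -> IsolatePhenotype:
    """Derive the QS/QQ category of one isolate.

    An isolate is a producer iff at least one biosensor is positive AND
    at least one produced AHL was confirmed by LC-MS/MS; it is a
    quencher iff it reduced at least one panel AHL to <= quench_threshold
    of the pH-matched control within the assay window. The category is
    producer / quencher / both / neither from those two flags.

    ``record`` is a mapping (e.g. a DataFrame row) with keys
    isolate_id, taxon, biosensor_<name>, produced_ahls (iterable or
    comma-separated string), residual_<ahl> and control_<ahl> for each
    panel AHL, and optionally control_ph.
    """
    ph = record.get("control_ph")
    if ph is not None and not pd.isna(ph) and float(ph) > max_control_ph:
        raise ControlQualityError(
            f"isolate {record.get('isolate_id')}: control pH {ph} exceeds "
            f"{max_control_ph}"
        )
    biosensors = {
        name: bool(record.get(f"biosensor_{name}", False)) for name in BIOSENSORS
    }
    produced = record.get("produced_ahls", "")
    if produced is None or (not isinstance(produced, str) and pd.isna(produced)):
        produced = ""
    if isinstance(produced, str):
        produced = frozenset(a.strip() for a in produced.split(",") if a.strip())
    else:
        produced = frozenset(produced)
    residual, control = {}, {}
    for ahl in QUENCH_PANEL:
        key = ahl.replace("-HSL", "")
        if f"residual_{key}" in record:
            residual[ahl] = float(record[f"residual_{key}"])
        if f"control_{key}" in record:
            control[ahl] = float(record[f"control_{key}"])
    quenched = quenched_set(residual, control, quench_threshold)

    is_producer = any(biosensors.values()) and bool(produced)
    is_quencher = bool(quenched)
    if is_producer and is_quencher:
        category = "both"
    elif is_producer:
        category = "producer"
    elif is_quencher:
        category = "quencher"
    else:
        category = "neither"
    return IsolatePhenotype(
        isolate_id=str(record.get("isolate_id", "")),
        taxon=str(record.get("taxon", "")),
        biosensor_positive=biosensors,
        produced_ahls=produced,
        residual_fraction=residual,
        control_residual=control,
        quenched_ahls=quenched,
        category=category,
    )


def screen_panel(
    table: pd.DataFrame,
    quench_threshold: float = 0.5,
    max_control_ph: float = MAX_CONTROL_PH,
) -> list[IsolatePhenotype]:
    """Classify every isolate row of an assay table; invalid controls are dropped."""
    phenotypes = []
    for _, row in table.iterrows():
        try:
            phenotypes.append(
                classify_isolate(row, quench_threshold, max_control_ph)
            )
        except ControlQualityError as exc:
            logger.warning("%s; isolate excluded", exc)
    return phenotypes


def summarize_categories(phenotypes: Sequence[IsolatePhenotype]) -> dict[str, float]:
    """Category percentages over all isolates.

    producer_any / quencher_any count isolates with the respective flag
    regardless of the other (so "both" is counted in each); the
    inclusion-exclusion identity either = producer_any + quencher_any -
    both = 100 - neither holds exactly.
    """
    if not phenotypes:
        raise ValueError("at least one phenotype required")
    n = len(phenotypes)
    producer_any = sum(p.category in ("producer", "both") for p in phenotypes)
    quencher_any = sum(p.category in ("quencher", "both") for p in phenotypes)
    both = sum(p.category == "both" for p in phenotypes)
    neither = sum(p.category == "neither" for p in phenotypes)
    pct = lambda x: 100.0 * x / n
    return {
        "producer_any": pct(producer_any),
        "quencher_any": pct(quencher_any),
        "both": pct(both),
        "neither": pct(neither),
        "either": pct(producer_any + quencher_any - both),
        "n": n,
    }


def quench_spectrum(phenotypes: Iterable[IsolatePhenotype]) -> dict[str, float]:
    """Degradation spectrum of the quenchers.

    Percentages (over quenchers) that degrade only the long-chain AHL
    (3OC12-HSL), that additionally degrade a short/medium-chain AHL, and
    that degrade the long-chain AHL at all.
    """
    quenchers = [p for p in phenotypes if p.category in ("quencher", "both")]
    if not quenchers:
        raise ValueError("no quenchers among the phenotypes")
    n = len(quenchers)
    degrades_long = sum(LONG_CHAIN in p.quenched_ahls for p in quenchers)
    long_plus = sum(
        LONG_CHAIN in p.quenched_ahls
        and any(a in p.quenched_ahls for a in SHORT_MEDIUM)
        for p in quenchers
    )
    long_only = sum(
        p.quenched_ahls == frozenset({LONG_CHAIN}) for p in quenchers
    )
    return {
        "long_only": 100.0 * long_only / n,
        "long_plus_short_or_medium": 100.0 * long_plus / n,
        "degrades_long": 100.0 * degrades_long / n,
        "n_quenchers": n,
    }


def phenotype_table(phenotypes: Sequence[IsolatePhenotype]) -> pd.DataFrame:
    """Tabulate phenotypes for TSV export."""
    return pd.DataFrame(
        {
            "isolate_id": [p.isolate_id for p in phenotypes],
            "taxon": [p.taxon for p in phenotypes],
            "produced_ahls": [",".join(sorted(p.produced_ahls)) for p in phenotypes],
            "quenched_ahls": [",".join(sorted(p.quenched_ahls)) for p in phenotypes],
            "category": [p.category for p in phenotypes],
        }
    )
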