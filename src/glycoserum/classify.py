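"""Composition-only structural classification of N-glycans.

Monosaccharide composition cannot resolve linkage, so the classes below are
heuristic but standard glycomics practice:

* high-mannose — HexNAc 2 (core only), Hex 5–9, no fucose or sialic acid;
* hybrid      — HexNAc 3 with Hex >= 5 (one processed arm, mannoses kept);
* complex     — HexNAc >= 4, or HexNAc 3 with Hex <= 4 (truncated
  mono-antennary complex);
* other       — everything else (e.g. paucimannose Hex3-4 HexNAc2).

Antennarity of a complex glycan is min(HexNAc - 2, 4); a Hex3 HexNAc5
composition without sialic acid is treated as a bisected (not
tri-antennary) agalactosyl bi-antennary structure, since composition alone
cannot distinguish a bisecting GlcNAc from a third antenna.  Galactose
count is Hex - 3 (the core contributes three mannoses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core import CompositionError, GlycanComposition, GlycanPanel

__all__ = [
    "StructuralClass",
    "classify_type",
    "antennae_count",
    "is_agalactosyl_biantennary",
    "is_highly_sialylated_multibranched",
    "slex_potential",
    "aggregate_abundance",
    "classification_report",
    "PREDICATES",
]

HIGH_MANNOSE = "high-mannose"
HYBRID = "hybrid"
COMPLEX = "complex"
OTHER = "other"


def _type_of(comp: GlycanComposition) -> str:
    if comp.hexnac == 2 and 5 <= comp.hex <= 9 and comp.fuc == 0 and comp.neuac == 0:
        return HIGH_MANNOSE
    if comp.hexnac == 3 and comp.hex >= 5:
        return HYBRID
    if comp.hexnac >= 4 or (comp.hexnac == 3 and comp.hex <= 4):
        return COMPLEX
    return OTHER


def antennae_count(comp: GlycanComposition) -> int:
    """Number of GlcNAc-initiated antennae of a complex composition (2-4).

    ``min(hexnac - 2, 4)`` with one override: Hex3 HexNAc5 without sialic
    acid is scored bi-antennary (bisecting GlcNAc assumption).
    """
    if _type_of(comp) != COMPLEX:
        raise CompositionError(f"{comp.code} is not complex type; antennae undefined")
    if comp.hexnac == 5 and comp.hex == 3 and comp.neuac == 0:
        return 2
    return min(comp.hexnac - 2, 4)


def is_agalactosyl_biantennary(comp: GlycanComposition) -> bool:
    """Complex bi-antennary glycan lacking terminal galactose (Hex == 3)."""
    if _type_of(comp) != COMPLEX:
        return False
    return antennae_count(comp) == 2 and comp.hex - 3 == 0


def is_highly_sialylated_multibranched(comp: GlycanComposition) -> bool:
    """Complex, tri- or tetra-antennary, carrying >= 3 sialic acids."""
    if _type_of(comp) != COMPLEX:
        return False
    return antennae_count(comp) >= 3 and comp.neuac >= 3


def slex_potential(comp: GlycanComposition) -> bool:
    """Could carry a sialyl Lewis X epitope: complex, sialylated, and with
    at least one fucose beyond the (assumed core-linked) first one."""
    return _type_of(comp) == COMPLEX and comp.neuac >= 1 and comp.fuc >= 2


@dataclass(frozen=True)
class StructuralClass:
    """Full structural annotation of one composition."""

    type: str
    antennae: int | None
    sialylated: bool
    fucosylated: bool
    agalactosyl_bi: bool
    highly_sialylated_multibranched: bool
    slex_potential: bool


def classify_type(comp: GlycanComposition) -> StructuralClass:
    """Classify a valid N-glycan composition; every input gets exactly one type."""
    if not comp.is_valid_nglycan():
        raise CompositionError(
            f"{comp.code} is not a valid N-glycan (requires hexnac >= 2 and hex >= 3)"
        )
    t = _type_of(comp)
    return StructuralClass(
        type=t,
        antennae=antennae_count(comp) if t == COMPLEX else None,
        sialylated=comp.neuac >= 1,
        fucosylated=comp.fuc >= 1,
        agalactosyl_bi=is_agalactosyl_biantennary(comp),
        highly_sialylated_multibranched=is_highly_sialylated_multibranched(comp),
        slex_potential=slex_potential(comp),
    )


def _antennae_pred(n: int) -> Callable[[GlycanComposition], bool]:
    return lambda c: _type_of(c) == COMPLEX and antennae_count(c) == n


#: Named class selectors usable with :func:`aggregate_abundance`.
PREDICATES: dict[str, Callable[[GlycanComposition], bool]] = {
    "all": lambda c: True,
    "high-mannose": lambda c: _type_of(c) == HIGH_MANNOSE,
    "hybrid": lambda c: _type_of(c) == HYBRID,
    "complex": lambda c: _type_of(c) == COMPLEX,
    "other": lambda c: _type_of(c) == OTHER,
    "sialylated": lambda c: c.neuac >= 1,
    "fucosylated": lambda c: c.fuc >= 1,
    "bi-antennary": _antennae_pred(2),
    "tri-antennary": _antennae_pred(3),
    "tetra-antennary": _antennae_pred(4),
    "agalactosyl_bi": is_agalactosyl_biantennary,
    "highly_sialylated_multibranched": is_highly_sialylated_multibranched,
    "slex_potential": slex_potential,
}


def aggregate_abundance(
    matrix: pd.DataFrame,
    panel: GlycanPanel,
    predicate: str | Callable[[GlycanComposition], bool],
) -> pd.Series:
    """Per-sample total abundance over panel glycans satisfying a predicate.

    ``matrix`` is samples x glycans with columns addressed by code or
    integer label; unknown columns raise with the offending names listed.
    """
    if isinstance(predicate, str):
        try:
            pred = PREDICATES[predicate]
            name = predicate
        except KeyError:
            raise KeyError(
                f"unknown predicate {predicate!r}; choose from {sorted(PREDICATES)}"
            ) from None
    else:
        pred, name = predicate, getattr(predicate, "__name__", "custom")
    unknown = [c for c in matrix.columns if c not in panel]
    if unknown:
        raise KeyError(f"matrix columns not in panel: {unknown}")
    cols = [c for c in matrix.columns if pred(panel.composition(c))]
    total = matrix[cols].sum(axis=1) if cols else pd.Series(0.0, index=matrix.index)
    total.name = name
    return total.astype(float)


def classification_report(panel: GlycanPanel) -> pd.DataFrame:
    """One row per panel glycan with its type, antennarity and flags."""
    rows = []
    for comp, label in zip(panel.compositions, panel.labels):
        sc = classify_type(comp)
        rows.append(
            {
                "code": comp.code,
                "label": label,
                "type": sc.type,
                "antennae": sc.antennae if sc.antennae is not None else np.nan,
                "sialylated": sc.sialylated,
                "fucosylated": sc.fucosylated,
                "agalactosyl_bi": sc.agalactosyl_bi,
                "highly_sialylated_multibranched": sc.highly_sialylated_multibranched,
                "slex_potential": sc.slex_potential,
            }
        )
    df = pd.DataFrame(rows)
    df["antennae"] = df["antennae"].astype("Int64")
    return df


def class_counts(panel: GlycanPanel) -> dict[str, int]:
    """Marginal class counts of a panel (the printed-summary quantities)."""
    report = classification_report(panel)
    complex_rows = report[report["type"] == COMPLEX]
    return {
        "n": len(report),
        "high_mannose": int((report["type"] == HIGH_MANNOSE).sum()),
        "hybrid": int((report["type"] == HYBRID).sum()),
        "complex": int(len(complex_rows)),
        "bi_antennary": int((complex_rows["antennae"] == 2).sum()),
        "tri_antennary": int((complex_rows["antennae"] == 3).sum()),
        "tetra_antennary": int((complex_rows["antennae"] == 4).sum()),
        "sialylated": int(report["sialylated"].sum()),
        "fucosylated": int(report["fucosylated"].sum()),
        "highly_sialylated_multibranched": int(
            report["highly_sialylated_multibranched"].sum()
        ),
        "agalactosyl_bi": int(report["agalactosyl_bi"].sum()),
    }


def validate_panel_counts(panel: GlycanPanel, expected: dict[str, int]) -> None:
    """Raise if the classifier's marginals on `panel` differ from `expected`."""
    got = class_counts(panel)
    errors = {k: (expected[k], got.get(k)) for k in expected if got.get(k) != expected[k]}
    if errors:
        raise ValueError(f"panel class counts disagree (expected, got): {errors}")
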