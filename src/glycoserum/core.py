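"""Composition codes, derivatization-aware masses, and peak annotation.

Serum N-glycans released by glycoblotting are sialic-acid methyl-esterified,
tagged at the reducing end with benzyloxyamine (BOA, an oxime adding C7H9NO
net of water) and detected by positive-mode MALDI-TOF as sodium adducts
[M+Na]+.  A glycan is identified here only by its monosaccharide
composition, written as a four-digit code counting, in order, hexose
(mannose/galactose), N-acetylhexosamine (GlcNAc), deoxyhexose (fucose) and
sialic acid (NeuAc) residues — e.g. ``5402`` is Hex5 HexNAc4 NeuAc2.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GlycanComposition",
    "MassModel",
    "DEFAULT_MASS_MODEL",
    "GlycanPeak",
    "AnnotatedGlycan",
    "GlycanPanel",
    "ParseError",
    "CompositionError",
    "parse_code",
    "format_code",
    "theoretical_mz",
    "peak_label",
    "enumerate_compositions",
    "annotate_peaks",
    "read_peak_list",
]

RESIDUE_KINDS = ("hex", "hexnac", "fuc", "neuac")

# Monoisotopic residue masses (dehydrated, i.e. as incorporated in the chain).
MASS_HEX = 162.052824
MASS_HEXNAC = 203.079373
MASS_FUC = 146.057909
MASS_NEUAC = 291.095417
MASS_METHYL_ESTER = 14.015650   # CH2, per methyl-esterified sialic acid
MASS_BOA_TAG = 123.068414       # C7H9NO, benzyloxyamine oxime net addition
MASS_NA = 22.989769             # sodium cation adduct


class ParseError(ValueError):
    """Malformed composition code."""


class CompositionError(ValueError):
    """Composition is not a valid N-glycan for the requested operation."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of the four residue kinds of an N-glycan composition.

    Ordering is lexicographic by (hex, hexnac, fuc, neuac), which is also
    the deterministic order used by :func:`enumerate_compositions`.
    """

    hex: int
    hexnac: int
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for kind in RESIDUE_KINDS:
            v = getattr(self, kind)
            if not isinstance(v, int) or v < 0:
                raise ParseError(f"residue count {kind}={v!r} must be a non-negative integer")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.fuc, self.neuac)

    @property
    def total_residues(self) -> int:
        return sum(self.counts)

    def is_valid_nglycan(self) -> bool:
        """True if the composition can sit on a trimannosyl-chitobiose core."""
        return self.hexnac >= 2 and self.hex >= 3

    def add(self, kind: str, n: int = 1) -> "GlycanComposition":
        if kind not in RESIDUE_KINDS:
            raise ValueError(f"unknown residue kind {kind!r}")
        return replace(self, **{kind: getattr(self, kind) + n})

    @property
    def code(self) -> str:
        return format_code(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_code(code: str) -> GlycanComposition:
    """Parse a four-digit (or dash-separated) composition code.

    The four numbers count Hex, HexNAc, Fuc and NeuAc in this order.
    ``"5402"`` and ``"5-4-0-2"`` both parse to Hex5 HexNAc4 NeuAc2; the
    dash-separated form exists for counts >= 10.
    """
    code = str(code).strip()
    if "-" in code:
        tokens = code.split("-")
    else:
        tokens = list(code)
    if len(tokens) != 4:
        raise ParseError(
            f"composition code {code!r} must have 4 tokens (got {len(tokens)})"
        )
    counts = []
    for kind, tok in zip(RESIDUE_KINDS, tokens):
        if not re.fullmatch(r"\d+", tok):
            raise ParseError(f"token {tok!r} for {kind} in code {code!r} is not a non-negative integer")
        counts.append(int(tok))
    return GlycanComposition(*counts)


def format_code(comp: GlycanComposition) -> str:
    """Canonical code: 4 contiguous digits, dash-separated if any count >= 10."""
    if max(comp.counts) >= 10:
        return "-".join(str(c) for c in comp.counts)
    return "".join(str(c) for c in comp.counts)


@dataclass(frozen=True)
class MassModel:
    """Mass model for BOA-tagged, methyl-esterified glycans as [M+Na]+.

    theoretical m/z = sum(residue masses) + neuac * methyl_ester
                      + boa_tag + cation

    The sodium adduct (no electron-mass correction) reproduces the
    smallest panel mass Hex5HexNAc2 = 1362.481 to three decimals.
    """

    hex: float = MASS_HEX
    hexnac: float = MASS_HEXNAC
    fuc: float = MASS_FUC
    neuac: float = MASS_NEUAC
    methyl_ester: float = MASS_METHYL_ESTER
    boa_tag: float = MASS_BOA_TAG
    cation: float = MASS_NA
    tolerance: float = 0.2  # Da, annotation match window

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac", "methyl_ester", "boa_tag", "cation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"mass {name} must be strictly positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    def residue_delta(self, kind: str) -> float:
        """Mass added by one more residue of `kind` (NeuAc incl. methyl ester)."""
        base = getattr(self, kind)
        if kind == "neuac":
            base += self.methyl_ester
        return base


DEFAULT_MASS_MODEL = MassModel()


def theoretical_mz(comp: GlycanComposition, model: MassModel = DEFAULT_MASS_MODEL) -> float:
    """Theoretical monoisotopic [M+Na]+ m/z of a derivatized composition."""
    if not comp.is_valid_nglycan():
        raise CompositionError(
            f"{comp.code} is not a valid N-glycan (requires hexnac >= 2 and hex >= 3)"
        )
    return (
        comp.hex * model.hex
        + comp.hexnac * model.hexnac
        + comp.fuc * model.fuc
        + comp.neuac * (model.neuac + model.methyl_ester)
        + model.boa_tag
        + model.cation
    )


def peak_label(comp: GlycanComposition, model: MassModel = DEFAULT_MASS_MODEL) -> int:
    """Integer peak name, floor of the theoretical m/z (e.g. 2378 for 5402)."""
    return math.floor(theoretical_mz(comp, model))


def enumerate_compositions(
    mass_window: tuple[float, float],
    bounds: tuple[int, int, int, int] = (9, 7, 4, 4),
    model: MassModel = DEFAULT_MASS_MODEL,
) -> list[GlycanComposition]:
    """All valid N-glycan compositions with theoretical m/z in [lo, hi].

    Brute-force over the bounded count grid, returned in lexicographic
    order by (hex, hexnac, fuc, neuac).
    """
    lo, hi = mass_window
    if lo >= hi:
        raise ValueError(f"mass window [{lo}, {hi}] must satisfy lo < hi")
    out: list[GlycanComposition] = []
    for h in range(3, bounds[0] + 1):
        for n in range(2, bounds[1] + 1):
            for f in range(0, bounds[2] + 1):
                for s in range(0, bounds[3] + 1):
                    comp = GlycanComposition(h, n, f, s)
                    if lo <= theoretical_mz(comp, model) <= hi:
                        out.append(comp)
    return sorted(out)


@dataclass(frozen=True)
class GlycanPeak:
    """A detected MALDI-TOF peak: observed m/z with intensity or quantity."""

    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be > 0 (got {self.mz})")
        if self.intensity <= 0:
            raise ValueError(f"peak intensity must be > 0 (got {self.intensity})")


@dataclass(frozen=True)
class AnnotatedGlycan:
    """A peak matched to a composition within the mass tolerance."""

    composition: GlycanComposition
    theoretical_mz: float
    label: int
    peak: GlycanPeak | None = None

    @property
    def code(self) -> str:
        return self.composition.code


def annotate_peaks(
    peaks: Sequence[GlycanPeak],
    candidates: Sequence[GlycanComposition],
    model: MassModel = DEFAULT_MASS_MODEL,
) -> tuple[list[AnnotatedGlycan], list[GlycanPeak]]:
    """Greedily match peaks to candidate compositions by mass distance.

    Pairs within ``model.tolerance`` are assigned smallest-distance first;
    each peak takes at most one candidate and each candidate annotates at
    most one peak.  Ties on distance are broken by fewest total residues,
    then lexicographic counts, so the result is independent of input order.
    Returns (annotations, unmatched peaks).
    """
    cand = sorted(set(candidates))
    cand_mz = [theoretical_mz(c, model) for c in cand]
    # all admissible (distance, tie-break, candidate idx, peak idx) pairs
    pairs = []
    for pi, p in enumerate(peaks):
        for ci, (c, mz) in enumerate(zip(cand, cand_mz)):
            d = abs(p.mz - mz)
            if d <= model.tolerance:
                pairs.append((d, c.total_residues, c.counts, ci, pi))
    pairs.sort()
    used_c: set[int] = set()
    used_p: set[int] = set()
    hits: dict[int, AnnotatedGlycan] = {}
    for d, _, _, ci, pi in pairs:
        if ci in used_c or pi in used_p:
            continue
        used_c.add(ci)
        used_p.add(pi)
        c = cand[ci]
        if d > 1e-3:
            log.debug("peak %.4f annotated as %s (Δ=%.4f Da)", peaks[pi].mz, c.code, d)
        hits[pi] = AnnotatedGlycan(
            composition=c,
            theoretical_mz=cand_mz[ci],
            label=math.floor(cand_mz[ci]),
            peak=peaks[pi],
        )
    annotated = [hits[pi] for pi in sorted(hits)]
    unmatched = [p for pi, p in enumerate(peaks) if pi not in used_p]
    for p in unmatched:
        log.warning("peak m/z %.4f unmatched within ±%.3g Da", p.mz, model.tolerance)
    # stable, order-independent presentation: by theoretical mass
    annotated.sort(key=lambda a: (a.theoretical_mz, a.composition.counts))
    unmatched.sort(key=lambda p: (p.mz, p.intensity))
    return annotated, unmatched


def read_peak_list(path: str | Path, delimiter: str | None = None) -> list[GlycanPeak]:
    """Read a two-column (m/z, intensity) peak list; '#' lines are comments."""
    peaks: list[GlycanPeak] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split(delimiter) if delimiter else re.split(r"[,\t\s]+", line)
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            peaks.append(GlycanPeak(mz=float(tokens[0]), intensity=float(tokens[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


class GlycanPanel:
    """An ordered set of annotated compositions with unique codes and labels.

    The panel is the fixed universe of glycans an abundance matrix refers
    to; columns may be addressed either by composition code ("5402") or by
    integer peak label (2378).
    """

    def __init__(
        self,
        compositions: Iterable[GlycanComposition],
        model: MassModel = DEFAULT_MASS_MODEL,
    ) -> None:
        comps = list(compositions)
        codes = [c.code for c in comps]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate composition codes in panel: {dupes}")
        self.model = model
        self.compositions: tuple[GlycanComposition, ...] = tuple(comps)
        self.mz: tuple[float, ...] = tuple(theoretical_mz(c, model) for c in comps)
        self.labels: tuple[int, ...] = tuple(math.floor(m) for m in self.mz)
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate integer labels in panel: {dupes}")
        self._by_code = {c.code: i for i, c in enumerate(comps)}
        self._by_label = {l: i for i, l in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.compositions)

    def __iter__(self):
        return iter(self.compositions)

    def __contains__(self, key) -> bool:
        try:
            self.resolve(key)
            return True
        except KeyError:
            return False

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.compositions)

    def resolve(self, key) -> str:
        """Map a code, integer label, or label-like string to the panel code."""
        s = str(key).strip()
        if s in self._by_code:
            return s
        try:
            lab = int(s)
        except ValueError:
            raise KeyError(f"unknown glycan identifier {key!r}") from None
        if lab in self._by_label:
            return self.compositions[self._by_label[lab]].code
        raise KeyError(f"unknown glycan identifier {key!r}")

    def composition(self, key) -> GlycanComposition:
        return self.compositions[self._by_code[self.resolve(key)]]

    def label(self, key) -> int:
        return self.labels[self._by_code[self.resolve(key)]]

    def theoretical_mz_of(self, key) -> float:
        return self.mz[self._by_code[self.resolve(key)]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": self.codes,
                "hex": [c.hex for c in self.compositions],
                "hexnac": [c.hexnac for c in self.compositions],
                "fuc": [c.fuc for c in self.compositions],
                "neuac": [c.neuac for c in self.compositions],
                "theoretical_mz": [round(m, 6) for m in self.mz],
                "label": self.labels,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path, model: MassModel = DEFAULT_MASS_MODEL) -> "GlycanPanel":
        df = pd.read_csv(path, dtype={"code": str})
        comps = [parse_code(code) for code in df["code"]]
        panel = cls(comps, model=model)
        if "theoretical_mz" in df.columns:
            for code, stored, computed in zip(panel.codes, df["theoretical_mz"], panel.mz):
                if abs(float(stored) - computed) > 5e-3:
                    raise ValueError(
                        f"panel file {path}: stored m/z {stored} for {code} "
                        f"disagrees with mass model ({computed:.6f})"
                    )
        return panel
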