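"""Encoding of experimental descriptors into the model's variable system.

The yield model is linear in log10 space:

    log10 Y = b0 + b_PRI * PRI + b_SEC * SEC + sum_j b_j * X_j

where PRI and SEC are effective enzymatic step counts of the primary
(substrate -> central precursor) and secondary (precursor -> product)
pathway segments, and the X_j are 0/1 indicators for the non-reference
levels of the six ordinal condition variables (OVE_C2, OVE_C3, KNO_C2,
NUT_C2, INT_C2, CUL_C2, OXY_C2).  Every category-1 level is absorbed into
the intercept, so no reference-level columns appear in the design.

When an intermediate precursor is co-fed (INT = C2) the carbon in the
product cannot be attributed to one source, so both the yield and the
step counts are taken as the arithmetic mean of the substrate-side and
intermediate-side bookkeeping (:func:`blended_yield`,
:func:`effective_steps`).

Step counting itself (which enzymes are on the key route) is a user
responsibility: count the enzymatic steps on the key route from the major
carbon substrate to the product, splitting at the central-metabolism
precursor, and neglect cofactor/ATP regeneration steps.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import ProductionRecord
from .exceptions import DomainError

__all__ = [
    "CategoryProfile",
    "EncodedRow",
    "ModelVariant",
    "INDICATOR_TERMS",
    "assign_categories",
    "effective_steps",
    "carbon_yield",
    "blended_yield",
    "reclassify_ethanol",
    "encode_record",
    "build_design",
    "profile_indicators",
]

#: Indicator columns in canonical design order.
INDICATOR_TERMS = ("OVE_C2", "OVE_C3", "KNO_C2", "NUT_C2", "INT_C2",
                   "CUL_C2", "OXY_C2")

#: Products treated as ethanol by :func:`reclassify_ethanol`.
ETHANOL_PRODUCTS = ("ethanol",)


class ModelVariant(enum.Enum):
    """The three published variants of the yield model.

    * ``MODEL1_WITH_PRI`` — full model with the PRI term.
    * ``MODEL2_NO_PRI`` — PRI dropped (it is statistically insignificant).
    * ``MODEL3_ETHANOL_PRIMARY`` — ethanol's pyruvate-to-ethanol secondary
      steps re-classified as primary metabolism before fitting, reflecting
      yeast's evolved fermentative robustness.
    """

    MODEL1_WITH_PRI = "model1"
    MODEL2_NO_PRI = "model2"
    MODEL3_ETHANOL_PRIMARY = "model3"

    @property
    def includes_pri(self) -> bool:
        return self is not ModelVariant.MODEL2_NO_PRI

    @property
    def ethanol_reclassified(self) -> bool:
        return self is ModelVariant.MODEL3_ETHANOL_PRIMARY

    @property
    def terms(self) -> tuple[str, ...]:
        """Design column names in canonical order."""
        head = ("Intercept", "PRI") if self.includes_pri else ("Intercept",)
        return head + ("SEC",) + INDICATOR_TERMS

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        name = name.strip().lower()
        for v in cls:
            if name in (v.value, v.name.lower()):
                return v
        raise DomainError(f"unknown model variant {name!r}")


@dataclass(frozen=True)
class CategoryProfile:
    """Assigned levels of the six ordinal condition variables."""

    ove: str = "C1"
    kno: str = "C1"
    nut: str = "C1"
    int_add: str = "C1"
    cul: str = "C1"
    oxy: str = "C1"

    def __post_init__(self):
        if self.ove not in ("C1", "C2", "C3"):
            raise DomainError(f"OVE level must be C1/C2/C3, got {self.ove!r}")
        for name, val in (("KNO", self.kno), ("NUT", self.nut),
                          ("INT", self.int_add), ("CUL", self.cul),
                          ("OXY", self.oxy)):
            if val not in ("C1", "C2"):
                raise DomainError(f"{name} level must be C1/C2, got {val!r}")

    def as_tuple(self) -> tuple[str, ...]:
        return (self.ove, self.kno, self.nut, self.int_add, self.cul, self.oxy)


@dataclass(frozen=True)
class EncodedRow:
    """One corpus record mapped onto the model's variables."""

    y_log10: float
    pri_eff: float
    sec_eff: float
    indicators: tuple[int, ...]  # ordered as INDICATOR_TERMS


_RICH_TOKENS = {"rich", "very rich", "complex"}
_DEFINED_TOKENS = {"defined", "minimal", "synthetic"}
_BIOREACTOR_TOKENS = {"bioreactor", "batch", "fed-batch", "fedbatch",
                      "continuous", "chemostat"}
_FLASK_TOKENS = {"flask", "shake flask", "shaking flask", "tube"}
_LIMITED_TOKENS = {"anaerobic", "micro-aerobic", "microaerobic",
                   "oxygen-limited", "oxygen limited"}
_AEROBIC_TOKENS = {"aerobic"}


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"yes", "true", "1", "y"}
    return bool(value)


def assign_categories(descriptor: Mapping | None = None, *,
                      modified_genes: int | None = None,
                      knockouts: int | None = None,
                      medium: str | None = None,
                      intermediate=None,
                      vessel: str | None = None,
                      aeration: str | None = None) -> CategoryProfile:
    """Map a free-form condition descriptor onto category levels.

    The rules: OVE is C1 with no modified genes/pathways, C2 with one or
    two, C3 with more than two; KNO is C2 iff any competing-pathway
    knockout was made; NUT is C2 for a rich medium; INT is C2 iff a
    pathway intermediate was fed; CUL is C2 for any bioreactor (batch,
    fed-batch or continuous) vs a shaking flask; OXY is C2 under
    oxygen-limited (anaerobic or micro-aerobic) conditions.

    Accepts either a mapping with keys ``modified_genes, knockouts,
    medium, intermediate, vessel, aeration`` or the same as keyword
    arguments.
    """
    if descriptor is not None:
        d = dict(descriptor)
        modified_genes = d.pop("modified_genes", modified_genes)
        knockouts = d.pop("knockouts", knockouts)
        medium = d.pop("medium", medium)
        intermediate = d.pop("intermediate", intermediate)
        vessel = d.pop("vessel", vessel)
        aeration = d.pop("aeration", aeration)
        if d:
            raise DomainError(f"unknown descriptor keys: {sorted(d)}")
    for name, val in (("modified_genes", modified_genes),
                      ("knockouts", knockouts)):
        if val is None:
            raise DomainError(f"descriptor field {name!r} is required")
        if val < 0:
            raise DomainError(f"{name} must be >= 0, got {val}")
    if modified_genes == 0:
        ove = "C1"
    elif modified_genes <= 2:
        ove = "C2"
    else:
        ove = "C3"
    kno = "C2" if knockouts > 0 else "C1"

    medium_t = (medium or "defined").strip().lower()
    if medium_t in _RICH_TOKENS:
        nut = "C2"
    elif medium_t in _DEFINED_TOKENS:
        nut = "C1"
    else:
        raise DomainError(f"unrecognized medium {medium!r}")

    int_add = "C2" if _as_bool(intermediate) else "C1"

    vessel_t = (vessel or "flask").strip().lower()
    if vessel_t in _BIOREACTOR_TOKENS:
        cul = "C2"
    elif vessel_t in _FLASK_TOKENS:
        cul = "C1"
    else:
        raise DomainError(f"unrecognized vessel {vessel!r}")

    aeration_t = (aeration or "aerobic").strip().lower()
    if aeration_t in _LIMITED_TOKENS:
        oxy = "C2"
    elif aeration_t in _AEROBIC_TOKENS:
        oxy = "C1"
    else:
        raise DomainError(f"unrecognized aeration {aeration!r}")

    return CategoryProfile(ove=ove, kno=kno, nut=nut, int_add=int_add,
                           cul=cul, oxy=oxy)


def effective_steps(substrate_steps: float,
                    intermediate_steps: float | None,
                    int_add: str) -> float:
    """Effective step count: the substrate-side count, or the arithmetic
    mean of substrate-side and intermediate-side counts when an
    intermediate is fed (INT = C2)."""
    if substrate_steps < 0:
        raise DomainError(f"substrate_steps must be >= 0, got {substrate_steps}")
    if int_add == "C2":
        if intermediate_steps is None:
            raise DomainError("INT = C2 requires an intermediate-side step count")
        if intermediate_steps < 0:
            raise DomainError(
                f"intermediate_steps must be >= 0, got {intermediate_steps}")
        return (substrate_steps + intermediate_steps) / 2.0
    return float(substrate_steps)


def carbon_yield(product_mol: float, carbons_per_product: float,
                 substrate_mol: float, carbons_per_substrate: float) -> float:
    """C-mol yield: (mol product x carbons/product) / (mol substrate x
    carbons/substrate).

    Based on initially added substrate and final measured product; unused
    residual substrate is not credited back.  A result above 1 usually
    means a co-substrate contributed carbon; it is returned with a warning
    rather than rejected.
    """
    for name, val in (("product_mol", product_mol),
                      ("carbons_per_product", carbons_per_product),
                      ("substrate_mol", substrate_mol),
                      ("carbons_per_substrate", carbons_per_substrate)):
        if not val > 0:
            raise DomainError(f"{name} must be > 0, got {val}")
    y = (product_mol * carbons_per_product) / (substrate_mol * carbons_per_substrate)
    if y > 1:
        warnings.warn(
            f"C-mol yield {y:.4g} exceeds 1; a co-substrate probably "
            "contributed carbon", stacklevel=2)
    return y


def blended_yield(yield_from_substrate: float,
                  yield_from_intermediate: float) -> float:
    """Arithmetic mean of the substrate-based and intermediate-based
    yields, used when carbon from the two sources cannot be distinguished."""
    for name, val in (("yield_from_substrate", yield_from_substrate),
                      ("yield_from_intermediate", yield_from_intermediate)):
        if not (0 < val <= 1):
            raise DomainError(f"{name} must be in (0, 1], got {val}")
    return (yield_from_substrate + yield_from_intermediate) / 2.0


def reclassify_ethanol(record: ProductionRecord,
                       core_secondary_steps: float = 2,
                       products: Sequence[str] = ETHANOL_PRODUCTS,
                       ) -> ProductionRecord:
    """Move ethanol's core fermentative steps from secondary to primary.

    For records whose product matches ``products`` (case-insensitive),
    up to ``core_secondary_steps`` steps (the pyruvate -> acetaldehyde ->
    ethanol pair by default) are moved from the secondary to the primary
    count, on both the substrate and intermediate side when present.
    Non-matching records are returned unchanged.  pri + sec is conserved.
    """
    if record.product.strip().lower() not in {p.lower() for p in products}:
        return record
    moved = min(core_secondary_steps, record.sec_substrate)
    kwargs = dict(
        pri_substrate=record.pri_substrate + moved,
        sec_substrate=record.sec_substrate - moved,
    )
    if record.sec_intermediate is not None:
        moved_i = min(core_secondary_steps, record.sec_intermediate)
        kwargs["sec_intermediate"] = record.sec_intermediate - moved_i
        kwargs["pri_intermediate"] = (record.pri_intermediate or 0.0) + moved_i
    return replace(record, **kwargs)


def profile_indicators(profile: CategoryProfile) -> tuple[int, ...]:
    """0/1 indicator values for a profile, ordered as INDICATOR_TERMS."""
    return (
        int(profile.ove == "C2"), int(profile.ove == "C3"),
        int(profile.kno == "C2"), int(profile.nut == "C2"),
        int(profile.int_add == "C2"), int(profile.cul == "C2"),
        int(profile.oxy == "C2"),
    )


def encode_record(record: ProductionRecord) -> EncodedRow:
    """Encode one record: log10 yield, effective steps, indicators."""
    if not record.yield_c > 0:
        raise DomainError(
            f"yield_c must be > 0 to take log10, got {record.yield_c} "
            f"({record.product})")
    profile = CategoryProfile(ove=record.ove, kno=record.kno, nut=record.nut,
                              int_add=record.int_add, cul=record.cul,
                              oxy=record.oxy)
    return EncodedRow(
        y_log10=math.log10(record.yield_c),
        pri_eff=effective_steps(record.pri_substrate, record.pri_intermediate,
                                record.int_add),
        sec_eff=effective_steps(record.sec_substrate, record.sec_intermediate,
                                record.int_add),
        indicators=profile_indicators(profile),
    )


def build_design(records: Iterable[ProductionRecord],
                 variant: ModelVariant = ModelVariant.MODEL1_WITH_PRI,
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Build the design matrix and log10-yield response for a variant.

    Columns in fixed order: Intercept, [PRI], SEC, OVE_C2, OVE_C3, KNO_C2,
    NUT_C2, INT_C2, CUL_C2, OXY_C2.  MODEL3 applies the ethanol
    re-classification before encoding.
    """
    records = list(records)
    if not records:
        raise DomainError("cannot build a design from an empty corpus")
    if variant.ethanol_reclassified:
        records = [reclassify_ethanol(r) for r in records]
    rows, y = [], []
    for r in records:
        enc = encode_record(r)
        head = [1.0, enc.pri_eff] if variant.includes_pri else [1.0]
        rows.append(head + [enc.sec_eff] + list(enc.indicators))
        y.append(enc.y_log10)
    design = pd.DataFrame(rows, columns=list(variant.terms), dtype=float)
    response = pd.Series(y, name="log10_yield", dtype=float)
    return design, response


def export_design(design: pd.DataFrame, response: pd.Series, path,
                  sep: str = "\t") -> None:
    """Write the encoded design + response as a numeric text matrix."""
    out = design.copy()
    out[response.name or "log10_yield"] = response.values
    out.to_csv(path, sep=sep, index=False)
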