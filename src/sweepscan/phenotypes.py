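"""Phenotype-threshold group assignment.

Builds test/control contrasts from a phenotype table the way the study
design defines them: pelt length thresholds on females only, nap-size
categories collapsed into short vs long, fur-quality grade cut-offs, and
color-types each compared against the wild-type black.  Category and
grade mappings are parameters because intermediate classes are excluded
by design rather than assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datamodel import GroupContrast, ValidationError

#: Nap categories run 1 (extra short) .. 8 (medium-long); the extremes
#: form the contrast and intermediates are excluded.
DEFAULT_NAP_TEST = frozenset({1, 2})
DEFAULT_NAP_CONTROL = frozenset({6, 7, 8})

PELT_LARGE_MIN_CM = 77.0
PELT_SMALL_MAX_CM = 59.0


@dataclass(frozen=True)
class PhenotypeRecord:
    """One animal's phenotypes; unknown traits stay ``None``."""

    sample_id: str
    sex: str | None = None  # "F" / "M"
    nap_category: int | None = None
    fur_grade: int | None = None
    pelt_length_cm: float | None = None
    color: str | None = None  # black / pastel / stardust

    def __post_init__(self) -> None:
        if self.nap_category is not None and not 1 <= self.nap_category <= 8:
            raise ValidationError(
                f"{self.sample_id}: nap category must be 1..8, got {self.nap_category}")
        if self.pelt_length_cm is not None and self.pelt_length_cm <= 0:
            raise ValidationError(f"{self.sample_id}: pelt length must be positive")


@dataclass
class GroupingRules:
    """Tunable thresholds for :func:`assign_groups`."""

    pelt_large_min_cm: float = PELT_LARGE_MIN_CM
    pelt_small_max_cm: float = PELT_SMALL_MAX_CM
    nap_test_categories: frozenset[int] = DEFAULT_NAP_TEST
    nap_control_categories: frozenset[int] = DEFAULT_NAP_CONTROL
    fur_high_min_grade: int = 4
    fur_low_max_grade: int = 2


def assign_groups(records: list[PhenotypeRecord], trait: str,
                  rules: GroupingRules | None = None) -> list[GroupContrast]:
    """Build contrasts for one trait family.

    ``trait`` is one of ``pelt_size``, ``nap_size``, ``fur_quality`` or
    ``color``.  Pelt size uses females only: length above the large
    threshold is test, below the small threshold control, anything
    between (or male) is excluded.  Color yields two contrasts,
    Pastel_Black and Stardust_Black, with black always the control.
    """
    rules = rules or GroupingRules()
    if trait == "pelt_size":
        females = [r for r in records if r.sex == "F" and r.pelt_length_cm is not None]
        if not females:
            raise ValidationError("no female pelt-length records for pelt_size")
        test = tuple(r.sample_id for r in females
                     if r.pelt_length_cm > rules.pelt_large_min_cm)
        control = tuple(r.sample_id for r in females
                        if r.pelt_length_cm < rules.pelt_small_max_cm)
        return [_contrast("pelt_size", test, control,
                          "large (test) vs small (control) female pelts")]
    if trait == "nap_size":
        with_nap = [r for r in records if r.nap_category is not None]
        if not with_nap:
            raise ValidationError("no nap-category records for nap_size")
        test = tuple(r.sample_id for r in with_nap
                     if r.nap_category in rules.nap_test_categories)
        control = tuple(r.sample_id for r in with_nap
                        if r.nap_category in rules.nap_control_categories)
        return [_contrast("nap_size", test, control,
                          "short (test) vs long (control) nap")]
    if trait == "fur_quality":
        with_grade = [r for r in records if r.fur_grade is not None]
        if not with_grade:
            raise ValidationError("no fur-grade records for fur_quality")
        test = tuple(r.sample_id for r in with_grade
                     if r.fur_grade >= rules.fur_high_min_grade)
        control = tuple(r.sample_id for r in with_grade
                        if r.fur_grade <= rules.fur_low_max_grade)
        return [_contrast("fur_quality", test, control,
                          "high (test) vs low (control) fur quality")]
    if trait == "color":
        with_color = [r for r in records if r.color is not None]
        if not with_color:
            raise ValidationError("no color records")
        black = tuple(r.sample_id for r in with_color if r.color == "black")
        out = []
        for variant in ("pastel", "stardust"):
            test = tuple(r.sample_id for r in with_color if r.color == variant)
            out.append(_contrast(f"{variant.capitalize()}_Black", test, black,
                                 f"{variant} (test) vs black (control)"))
        return out
    raise ValidationError(f"unknown trait {trait!r}")


def _contrast(name: str, test: tuple[str, ...], control: tuple[str, ...],
              description: str) -> GroupContrast:
    if not test or not control:
        raise ValidationError(
            f"contrast {name!r}: a group came out empty (test={len(test)}, "
            f"control={len(control)})")
    return GroupContrast(name=name, test_samples=test, control_samples=control,
                         description=description)


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV; missing cells become ``None``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("phenotype table needs a sample_id column")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def get(key, cast):
            v = d.get(key)
            return None if v is None or pd.isna(v) else cast(v)

        records.append(PhenotypeRecord(
            sample_id=str(d["sample_id"]),
            sex=get("sex", str),
            nap_category=get("nap_category", int),
            fur_grade=get("fur_grade", int),
            pelt_length_cm=get("pelt_length_cm", float),
            color=get("color", str),
        ))
    return records
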