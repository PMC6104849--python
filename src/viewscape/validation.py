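"""Validation of photo content against viewshed-visible land cover.

Manually assigned photo labels (which land classes the image shows) are
compared with what the viewshed says is visible from the photo point,
class by class, as a pair of binary raters: percent agreement and
Cohen's kappa, which corrects the agreement for chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import ElevationGrid
from .intensity import composition
from .viewshed import ViewshedResult

__all__ = [
    "PhotoLabelRecord",
    "AgreementResult",
    "DEFAULT_TAG_TO_CODES",
    "LAND_CLASS_TAGS",
    "viewshed_presence",
    "kappa",
    "agreement_report",
    "relevance_summary",
]

#: Land-class tags compared against viewsheds; content tags (activities,
#: monuments, wildlife, weather) have no land-cover counterpart.
LAND_CLASS_TAGS = ("water", "beach", "urban", "forest", "wetland", "agriculture")

#: Editable mapping from label tags to land-cover class codes
#: (NLCD-style integers; 10 is this package's ocean code).
DEFAULT_TAG_TO_CODES: dict[str, tuple[int, ...]] = {
    "water": (10, 11),
    "beach": (31,),
    "urban": (21, 22, 23, 24),
    "forest": (41, 42, 43),
    "wetland": (90, 95),
    "agriculture": (81, 82),
}


@dataclass
class PhotoLabelRecord:
    photo_id: str
    labels: frozenset[str] = field(default_factory=frozenset)
    relevant: bool = True

    def __post_init__(self) -> None:
        self.labels = frozenset(self.labels)
        if not self.labels and self.relevant:
            # a relevant photo always depicts something; empty label sets
            # mark the non-relevant (ads, scans, indoor shots)
            raise ValueError(
                f"photo {self.photo_id!r}: relevant photos must carry >= 1 label"
            )


@dataclass
class AgreementResult:
    class_tag: str
    table: tuple[int, int, int, int]  # (both, photo-only, viewshed-only, neither)
    percent_agreement: float
    kappa: float


def viewshed_presence(
    vs: ViewshedResult,
    landcover: ElevationGrid,
    class_tag: str,
    min_fraction: float = 0.0,
    mapping: Mapping[str, tuple[int, ...]] | None = None,
) -> bool:
    """Is the class visible from this viewshed?

    True iff the class's fraction of visible cells reaches
    ``min_fraction``; the default 0 means any visible cell counts.
    """
    mapping = DEFAULT_TAG_TO_CODES if mapping is None else mapping
    if class_tag not in mapping:
        raise KeyError(
            f"unmapped class tag {class_tag!r}; known tags: {sorted(mapping)}"
        )
    rec = composition(vs, landcover)
    frac = sum(rec.class_fractions.get(code, 0.0) for code in mapping[class_tag])
    if min_fraction <= 0.0:
        return frac > 0.0
    return frac >= min_fraction


def kappa(table: Sequence[int]) -> float:
    """Cohen's kappa for a 2x2 agreement table ``(a, b, c, d)``.

    ``a`` both raters positive, ``b`` first only, ``c`` second only,
    ``d`` both negative.  kappa = (p_o - p_e)/(1 - p_e) with p_o the
    observed agreement and p_e the marginal-product chance agreement.
    When chance agreement is exact (p_e = 1) kappa is defined as 1 for
    perfect observed agreement and undefined otherwise.
    """
    a, b, c, d = (int(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("agreement table is empty")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError(
            "degenerate table: chance agreement is 1 but observed agreement "
            "is not; kappa is undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def agreement_report(
    photos: Sequence[PhotoLabelRecord],
    viewsheds: Mapping[str, ViewshedResult],
    landcover: ElevationGrid,
    mapping: Mapping[str, tuple[int, ...]] | None = None,
    min_fraction: float = 0.0,
    tags: Sequence[str] | None = None,
) -> list[AgreementResult]:
    """Per-class percent agreement and kappa, photo labels vs viewsheds.

    Only relevant photos carrying at least one land-class tag enter the
    comparison (content-only photos say nothing about land cover).
    """
    mapping = DEFAULT_TAG_TO_CODES if mapping is None else mapping
    tags = tuple(tags) if tags is not None else tuple(
        t for t in LAND_CLASS_TAGS if t in mapping
    )
    land_tags = set(mapping)
    usable = [
        p for p in photos if p.relevant and (p.labels & land_tags)
    ]
    results: list[AgreementResult] = []
    presence_cache: dict[tuple[str, str], bool] = {}
    for p in usable:
        if p.photo_id not in viewsheds:
            raise ValueError(f"photo {p.photo_id!r} has no computed viewshed")
    for tag in tags:
        a = b = c = d = 0
        for p in usable:
            key = (p.photo_id, tag)
            if key not in presence_cache:
                presence_cache[key] = viewshed_presence(
                    viewsheds[p.photo_id], landcover, tag, min_fraction, mapping
                )
            vs_has = presence_cache[key]
            ph_has = tag in p.labels
            if ph_has and vs_has:
                a += 1
            elif ph_has:
                b += 1
            elif vs_has:
                c += 1
            else:
                d += 1
        n = a + b + c + d
        results.append(
            AgreementResult(
                class_tag=tag,
                table=(a, b, c, d),
                percent_agreement=100.0 * (a + d) / n,
                kappa=kappa((a, b, c, d)),
            )
        )
    return results


def relevance_summary(photos: Sequence[PhotoLabelRecord]) -> dict[str, float]:
    """Counts and percentages of relevant vs non-relevant photos,
    percentages reported at one decimal as in the validation write-up."""
    n = len(photos)
    if n == 0:
        raise ValueError("no photo records")
    n_rel = sum(1 for p in photos if p.relevant)
    n_non = n - n_rel
    return {
        "n_total": n,
        "n_relevant": n_rel,
        "n_nonrelevant": n_non,
        "pct_relevant": round(100.0 * n_rel / n, 1),
        "pct_nonrelevant": round(100.0 * n_non / n, 1),
    }
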