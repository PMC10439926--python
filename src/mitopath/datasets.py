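"""Dataset-construction filters.

The training set (Dataset 1 in our nomenclature) is built from two curated
variant lists: "general" population variants (candidate neutrals) and
"disease" variants (candidate pathogenics, confirmed or reported). Variants
appearing in both lists are removed from both; neutrals additionally lose
any variant carrying the ACMG rarity code PM2 (rare enough to support
pathogenicity); synergistic or conflicting variants are excluded everywhere.

Specificity evaluation sets (Datasets 2/3-style) come from population
databases filtered on allele frequency in both homoplasmy and heteroplasmy.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from mitopath.datamodel import FeatureTable, LabeledDataset, Status, VariantRecord

logger = logging.getLogger(__name__)


def build_dataset1(
    general: Sequence[VariantRecord],
    disease: Sequence[VariantRecord],
    features: FeatureTable,
) -> LabeledDataset:
    """Assemble the labeled training set from curated variant lists.

    Neutral class: general variants minus overlap with disease variants and
    minus PM2 carriers. Pathogenic class: disease variants with confirmed or
    reported status, minus overlap with the general list. Synergistic or
    conflicting records never enter either class. Variants absent from the
    feature table are dropped with a warning. Order-independent: the result
    depends only on the variant *sets*.
    """
    general_keys = {r.key for r in general}
    disease_keys = {r.key for r in disease}
    overlap = general_keys & disease_keys

    neutral = {
        r.key: r
        for r in general
        if r.key not in overlap
        and "PM2" not in r.clingen_codes
        and not r.synergistic_or_conflicting
    }
    pathogenic = {
        r.key: r
        for r in disease
        if r.key not in overlap
        and r.status in (Status.confirmed, Status.reported)
        and not r.synergistic_or_conflicting
    }

    available = set(features.variant_ids)
    labels: dict[str, int] = {}
    n_absent = 0
    for key_map, label in ((neutral, 0), (pathogenic, 1)):
        for record in key_map.values():
            vid = record.variant_id
            if vid not in available:
                n_absent += 1
                continue
            labels[vid] = label
    if n_absent:
        logger.warning("%d filtered variants absent from feature table", n_absent)

    if not any(v == 0 for v in labels.values()) or not any(
        v == 1 for v in labels.values()
    ):
        raise ValueError(
            "dataset construction left an empty class "
            f"({sum(v == 0 for v in labels.values())} neutral, "
            f"{sum(v == 1 for v in labels.values())} pathogenic)"
        )

    # deterministic row order: sort by variant id
    ids = sorted(labels)
    return LabeledDataset(
        features.subset_rows(ids), pd.Series({i: labels[i] for i in ids})
    )


def filter_by_af(
    records: Sequence[VariantRecord],
    source: str,
    min_af: float,
    exclude: Iterable[tuple[int, str, str]] = (),
) -> list[VariantRecord]:
    """Keep records with homoplasmic AND heteroplasmic AF >= ``min_af``.

    ``min_af`` is a fraction (0.002% -> 2e-5); the boundary is inclusive.
    ``exclude`` drops specific variant keys (training-set overlaps,
    cross-dataset duplicates). Unknown sources are fatal.
    """
    known = set().union(*(r.af.keys() for r in records)) if records else set()
    if records and source not in known:
        raise ValueError(f"unknown AF source {source!r}; available: {sorted(known)}")
    excluded = set(exclude)
    kept = []
    for r in records:
        if r.key in excluded or source not in r.af:
            continue
        hom, het = r.af[source]
        if hom >= min_af and het >= min_af:
            kept.append(r)
    return kept


def parse_af_threshold(text: str) -> float:
    """Parse an AF threshold, accepting a '%' suffix ('0.002%' -> 2e-5)."""
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)
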