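"""Stratified uORF-form frequencies, type-attribute transitions and the
multi-variant association fraction.

Accessions are stratified either by an explicit group label (e.g. rice
subspecies) or by the latitude at which they were collected, binned into
15-degree intervals over [-90, 90).  Frequencies are occurrence fractions of
each identifier (or explicit "absent") per locus, in the total population
and per group; accessions excluded by the mORF-start screen leave the
denominator and are reported separately.

The three headline Level1 transitions compare the three-way gene type
attribute (uORF-free / Type1-only / Type2) either across splicing models of
the reference genome or across accessions against the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .uorf_finder import TYPE1_ONLY, TYPE2_CLASS, UORF_FREE
from .uorf_indexer import UORFForm

ABSENT = "absent"
UNASSIGNED_GROUP = "unassigned"

TRANSITION_T1_T2 = "Type1-only<->Type2"
TRANSITION_FREE_T1 = "uORF-free<->Type1-only"
TRANSITION_FREE_T2 = "uORF-free<->Type2"

_PAIR_TO_CLASS = {
    frozenset({TYPE1_ONLY, TYPE2_CLASS}): TRANSITION_T1_T2,
    frozenset({UORF_FREE, TYPE1_ONLY}): TRANSITION_FREE_T1,
    frozenset({UORF_FREE, TYPE2_CLASS}): TRANSITION_FREE_T2,
}

TRANSITION_CLASSES = (TRANSITION_T1_T2, TRANSITION_FREE_T1, TRANSITION_FREE_T2)


def transition_class(attr_a: str, attr_b: str) -> str | None:
    """Name of the transition class for an unordered attribute pair, or None
    when the attributes are equal."""
    if attr_a == attr_b:
        return None
    return _PAIR_TO_CLASS[frozenset({attr_a, attr_b})]


@dataclass(frozen=True)
class TransitionCall:
    gene_id: str
    context: str  # "splicing-models" | "accessions"
    attr_a: str
    attr_b: str
    transition: str


def latitude_bin(latitude: float, width: int = 15) -> str:
    """Closed-left/open-right latitude bin label, e.g. 37.4 -> '[30,45)'."""
    if not -90 <= latitude < 90:
        raise ValueError(f"latitude {latitude} outside [-90, 90)")
    lo = math.floor((latitude + 90) / width) * width - 90
    return f"[{lo},{lo + width})"


def make_groups(
    metadata: pd.DataFrame,
    mode: str = "latitude",
    bin_width: int = 15,
) -> dict[str, list[str]]:
    """Partition accessions into groups.

    ``metadata`` needs an ``accession_id`` column plus ``latitude`` (decimal
    degrees) for mode "latitude" or ``group_label`` for mode "label".
    Accessions with missing latitude go to an "unassigned" group that is
    reported but not binned.
    """
    groups: dict[str, list[str]] = {}
    if mode == "latitude":
        for _, row in metadata.iterrows():
            lat = row.get("latitude")
            if lat is None or (isinstance(lat, float) and math.isnan(lat)):
                groups.setdefault(UNASSIGNED_GROUP, []).append(row["accession_id"])
            else:
                groups.setdefault(latitude_bin(float(lat), bin_width), []).append(
                    row["accession_id"]
                )
    elif mode == "label":
        for _, row in metadata.iterrows():
            groups.setdefault(str(row["group_label"]), []).append(row["accession_id"])
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    return groups


def compute_frequencies(
    assignments: Mapping[str, Mapping[int, str]],
    groups: Mapping[str, Sequence[str]],
    screened_out: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-locus occurrence fractions of each identifier, stratified.

    ``assignments`` maps accession -> {locus anchor -> identifier string or
    "absent"}; every analyzed accession must carry an entry for every locus.
    Returns a long-format DataFrame with columns locus_anchor, identifier,
    group, fraction, count, group_size; the pseudo-group "total" covers the
    whole analyzed population.  Fractions at one locus sum to 1 within each
    group.  Accessions named in ``screened_out`` are excluded everywhere.
    """
    screened = set(screened_out)
    analyzed = [a for a in assignments if a not in screened]
    if not analyzed:
        raise ValueError("no analyzed accessions")
    loci = sorted({loc for a in analyzed for loc in assignments[a]})
    columns: dict[str, list[str]] = {"total": analyzed}
    for gname, members in groups.items():
        kept = [a for a in members if a in assignments and a not in screened]
        if not members:
            raise ValueError(f"group {gname!r} is empty")
        if kept:
            columns[gname] = kept
    rows = []
    for locus in loci:
        identifiers = sorted({assignments[a].get(locus, ABSENT) for a in analyzed})
        for gname, members in columns.items():
            size = len(members)
            for ident in identifiers:
                count = sum(
                    1 for a in members if assignments[a].get(locus, ABSENT) == ident
                )
                rows.append(
                    {
                        "locus_anchor": locus,
                        "identifier": ident,
                        "group": gname,
                        "fraction": count / size,
                        "count": count,
                        "group_size": size,
                    }
                )
    return pd.DataFrame(rows)


def splicing_model_transitions(
    gene_id: str, attributes: Mapping[str, str]
) -> list[TransitionCall]:
    """Transitions among the splicing models of one reference gene.

    ``attributes`` maps transcript id -> three-way attribute.  Every
    unordered attribute pair observed across the models yields one call; the
    pair is always one of the three headline classes.
    """
    attrs = list(attributes.values())
    seen: set[frozenset] = set()
    calls: list[TransitionCall] = []
    for i in range(len(attrs)):
        for j in range(i + 1, len(attrs)):
            cls = transition_class(attrs[i], attrs[j])
            pair = frozenset({attrs[i], attrs[j]})
            if cls is not None and pair not in seen:
                seen.add(pair)
                a, b = sorted(pair)
                calls.append(TransitionCall(gene_id, "splicing-models", a, b, cls))
    return calls


def population_transitions(
    gene_id: str,
    reference_attribute: str,
    accession_attributes: Mapping[str, str],
) -> tuple[list[TransitionCall], dict[str, int]]:
    """Transitions between each accession and the reference on one model.

    Returns (calls, counts): one call per transition class observed, plus
    the number of accessions falling in each class.
    """
    counts: dict[str, int] = {cls: 0 for cls in TRANSITION_CLASSES}
    for attr in accession_attributes.values():
        cls = transition_class(reference_attribute, attr)
        if cls is not None:
            counts[cls] += 1
    calls = []
    for cls in TRANSITION_CLASSES:
        if counts[cls]:
            a, b = sorted(_class_pair(cls))
            calls.append(TransitionCall(gene_id, "accessions", a, b, cls))
    return calls, counts


def _class_pair(cls: str) -> frozenset:
    for pair, name in _PAIR_TO_CLASS.items():
        if name == cls:
            return pair
    raise KeyError(cls)


def multi_variant_fraction(forms: Iterable[UORFForm]) -> float | None:
    """Fraction of distinct non-reference uORF forms associated with at
    least two causal SNPs/INDELs; None when there is no non-reference form."""
    unique: dict[tuple[int, str], UORFForm] = {}
    for form in forms:
        if form.n_causal > 0:
            unique.setdefault(form.key, form)
    if not unique:
        return None
    multi = sum(1 for f in unique.values() if f.n_causal >= 2)
    return multi / len(unique)
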