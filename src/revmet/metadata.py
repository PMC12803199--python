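"""Joining spectral matches to harmonized sample metadata and aggregating.

Metadata follows the ReDU-harmonized convention: one row per data file with
controlled-vocabulary taxonomy (``NCBITaxID|Name``), body part (UBERON
name), disease (DOID name) and sample role. Aggregation produces the
surfaces used to read a repository-scale search: per-group tallies, a
three-state head x tail presence matrix (no spectrum / no match / matched),
match-count matrices, and chain parity / saturation summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .conjugates import parse_tail_name
from .search import SpectralMatch, matches_to_frame

MISSING = "missing"
UNANNOTATED = "unannotated"

#: ReDU-style metadata column names accepted on input.
_REDU_COLUMNS = {
    "filename": "file_id",
    "NCBITaxonomy": "taxonomy",
    "UBERONBodyPartName": "body_part",
    "DOIDCommonName": "disease",
    "SampleType": "sample_role",
}


@dataclass(frozen=True)
class SampleMetadata:
    """Per-file ontology record."""

    file_id: str
    taxonomy: str = MISSING
    body_part: str = MISSING
    disease: str = MISSING
    sample_role: str = "sample"


def read_metadata(path) -> List[SampleMetadata]:
    """Read a ReDU-style metadata TSV; unknown fields become 'missing'."""
    frame = pd.read_csv(path, sep="\t", dtype=str).rename(columns=_REDU_COLUMNS)
    if "file_id" not in frame.columns:
        raise ValueError("metadata table must have a 'filename' column")
    records = []
    for _, row in frame.iterrows():
        records.append(
            SampleMetadata(
                file_id=row["file_id"],
                taxonomy=_clean(row.get("taxonomy")),
                body_part=_clean(row.get("body_part")),
                disease=_clean(row.get("disease")),
                sample_role=_clean(row.get("sample_role"), default="sample"),
            )
        )
    return records


def _clean(value, default: str = MISSING) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return default
    return str(value)


def join_matches(
    matches: Sequence[SpectralMatch],
    metadata: Sequence[SampleMetadata],
    body_part_synonyms: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Annotate each match with its file's metadata; nothing is dropped.

    Matches to files absent from the metadata table are kept with every
    ontology field set to 'unannotated'. ``body_part_synonyms`` optionally
    collapses labels (e.g. {'anal': 'feces-anal', 'feces': 'feces-anal'}).
    """
    seen: Set[str] = set()
    duplicates = sorted({m.file_id for m in metadata if m.file_id in seen or seen.add(m.file_id)})
    if duplicates:
        raise ValueError(f"duplicate file_id in metadata: {duplicates}")
    by_file = {m.file_id: m for m in metadata}
    frame = matches_to_frame(matches)
    annotations = []
    for file_id in frame["file"]:
        record = by_file.get(str(file_id).strip())
        if record is None:
            annotations.append((UNANNOTATED, UNANNOTATED, UNANNOTATED, UNANNOTATED))
        else:
            body_part = record.body_part
            if body_part_synonyms:
                body_part = body_part_synonyms.get(body_part, body_part)
            annotations.append((record.taxonomy, body_part, record.disease, record.sample_role))
    columns = ["taxonomy", "body_part", "disease", "sample_role"]
    frame[columns] = pd.DataFrame(annotations, index=frame.index, columns=columns)
    return frame


def annotate_compounds(frame: pd.DataFrame, library_entries: Sequence) -> pd.DataFrame:
    """Resolve each match's query_id to head/tail/chain descriptors.

    Unresolvable query ids are labeled 'unknown' rather than dropped, so
    partition totals stay conserved downstream.
    """
    lookup: Dict[str, Tuple[str, str, int, int]] = {}
    for entry in library_entries:
        tail = entry.target.tail
        lookup[entry.query_id] = (
            entry.target.head.name,
            tail.name,
            tail.carbons,
            tail.unsaturations,
        )
    rows = []
    for query_id in frame["query_id"]:
        if query_id in lookup:
            rows.append(lookup[query_id])
        else:
            rows.append(("unknown", "unknown", -1, -1))
    frame = frame.copy()
    columns = ["head", "tail", "carbons", "unsaturations"]
    frame[columns] = pd.DataFrame(rows, index=frame.index, columns=columns)
    return frame


NO_SPECTRUM = "no_spectrum"
NO_MATCH = "no_match"
MATCHED = "matched"


@dataclass
class AggregationReport:
    """Presence/count matrices over the head x tail grid plus group tables."""

    presence: pd.DataFrame  # head x tail -> {no_spectrum, no_match, matched}
    counts: pd.DataFrame  # head x tail -> match count (NaN where no spectrum)
    by_group: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_summary(self) -> dict:
        return {
            "n_matched_cells": int((self.presence == MATCHED).to_numpy().sum()),
            "n_no_match_cells": int((self.presence == NO_MATCH).to_numpy().sum()),
            "n_no_spectrum_cells": int((self.presence == NO_SPECTRUM).to_numpy().sum()),
            "total_matches": int(self.counts.fillna(0).to_numpy().sum()),
            "groups": {k: v.to_dict(orient="index") for k, v in self.by_group.items()},
        }


def presence_and_counts(
    annotated: pd.DataFrame,
    library_pairs: Iterable[Tuple[str, str]],
    heads: Sequence[str],
    tails: Sequence[str],
) -> AggregationReport:
    """Aggregate annotated matches over the full head x tail grid.

    ``library_pairs`` are the (head, tail) combinations with at least one
    library spectrum; grid cells outside that set are 'no_spectrum' with an
    undefined (NaN) count — distinguishable from a zero-match cell. Unique
    compounds collapse adducts and isomers of the same head x tail pair.
    """
    library_pairs = set(library_pairs)
    presence = pd.DataFrame(NO_SPECTRUM, index=list(heads), columns=list(tails))
    counts = pd.DataFrame(float("nan"), index=list(heads), columns=list(tails))
    for head, tail in library_pairs:
        presence.loc[head, tail] = NO_MATCH
        counts.loc[head, tail] = 0
    for (head, tail), group in annotated.groupby(["head", "tail"]):
        if (head, tail) in library_pairs:
            presence.loc[head, tail] = MATCHED
            counts.loc[head, tail] = len(group)

    by_group: Dict[str, pd.DataFrame] = {}
    for dimension in ("taxonomy", "body_part", "disease"):
        rows = {}
        for label, group in annotated.groupby(dimension):
            rows[label] = {
                "n_matches": len(group),
                "n_unique_compounds": group[["head", "tail"]].drop_duplicates().shape[0],
                "n_files": group["file"].nunique(),
            }
        by_group[dimension] = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    return AggregationReport(presence=presence, counts=counts, by_group=by_group)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def chain_class_summary(annotated: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Partition matches by chain parity and saturation, with per-tail shares.

    Returns tables 'parity', 'saturation' and 'tails'. A tail's percentage is
    its share of its parity class, rounded half-away-from-zero to integers
    (full precision retained in the 'fraction' column). Matches whose
    compound cannot be resolved are tallied under 'unknown'.
    """
    known = annotated[annotated["carbons"] > 0]
    unknown = len(annotated) - len(known)

    parity_label = known["carbons"].mod(2).map({0: "even", 1: "odd"})
    parity_counts = parity_label.value_counts().to_dict()
    parity = pd.DataFrame(
        {
            "n_matches": {
                "even": parity_counts.get("even", 0),
                "odd": parity_counts.get("odd", 0),
                "unknown": unknown,
            }
        }
    )

    saturated = (known["unsaturations"] == 0).map({True: "saturated", False: "unsaturated"})
    sat_counts = saturated.value_counts().to_dict()
    saturation = pd.DataFrame(
        {
            "n_matches": {
                "saturated": sat_counts.get("saturated", 0),
                "unsaturated": sat_counts.get("unsaturated", 0),
                "unknown": unknown,
            }
        }
    )

    tail_rows = []
    for tail, group in known.groupby("tail"):
        carbons = int(group["carbons"].iloc[0])
        parity_class = "even" if carbons % 2 == 0 else "odd"
        class_total = parity_counts.get(parity_class, 0)
        fraction = len(group) / class_total if class_total else 0.0
        tail_rows.append(
            {
                "tail": tail,
                "carbons": carbons,
                "unsaturations": int(group["unsaturations"].iloc[0]),
                "parity": parity_class,
                "n_matches": len(group),
                "fraction_of_parity_class": fraction,
                "percent_of_parity_class": _round_half_away(100.0 * fraction),
            }
        )
    tails = pd.DataFrame(
        tail_rows,
        columns=[
            "tail",
            "carbons",
            "unsaturations",
            "parity",
            "n_matches",
            "fraction_of_parity_class",
            "percent_of_parity_class",
        ],
    ).sort_values(["carbons", "unsaturations", "tail"]).reset_index(drop=True)
    return {"parity": parity, "saturation": saturation, "tails": tails}


def tally(counts: Mapping[str, int]) -> int:
    """Sum a per-category count table (adduct or repository bookkeeping)."""
    return int(sum(counts.values()))
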