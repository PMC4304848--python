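"""Variant feature vectors for activity classification.

Each single-residue variant is encoded as 27 input attributes: the mutated
position and the native/replacement identities, the residual score, then
EP scores / identities / sequence offsets of the six nearest tessellation
neighbors (ordered by Cα–Cα edge length), and finally five attributes of
the mutated site itself — mean volume and mean tetrahedrality of its
incident tetrahedra, secondary structure (H/S/C), tessellation depth
(S/U/B), and the number of edges shared with surface positions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mutagenesis import Variant, residual_profile
from .potential import QuadrupletPotential
from .structure_io import AMINO_ACIDS, ProteinStructure
from .tessellation import (Tessellation, classify_depth, surface_edge_count,
                           tetrahedron_geometry)

#: ordered attribute names; exactly 27 entries
FEATURE_COLUMNS: tuple[str, ...] = (
    "position", "native", "replacement", "residual_score",
    "ep_n1", "ep_n2", "ep_n3", "ep_n4", "ep_n5", "ep_n6",
    "aa_n1", "aa_n2", "aa_n3", "aa_n4", "aa_n5", "aa_n6",
    "offset_n1", "offset_n2", "offset_n3", "offset_n4", "offset_n5", "offset_n6",
    "mean_volume", "mean_tetrahedrality",
    "secondary_structure", "depth", "surface_edges",
)

CATEGORICAL_COLUMNS: tuple[str, ...] = (
    "native", "replacement",
    "aa_n1", "aa_n2", "aa_n3", "aa_n4", "aa_n5", "aa_n6",
    "secondary_structure", "depth",
)

NUMERIC_COLUMNS: tuple[str, ...] = tuple(
    c for c in FEATURE_COLUMNS if c not in CATEGORICAL_COLUMNS)

#: sentinel identity for padded neighbor slots
PAD_AA = "-"


def nearest_six_neighbors(tess: Tessellation, position: int
                          ) -> list[tuple[int, float]]:
    """Up to six neighbor positions ordered by ascending Cα–Cα edge length.

    Distance ties are broken by ascending sequence number. Positions with
    fewer than six tessellation neighbors return a shorter list (padding is
    applied when the feature vector is assembled).
    """
    idx = tess.index_of(position)
    pairs = [(tess.positions[j], d) for j, d in tess.vertex_edges(idx).items()]
    pairs.sort(key=lambda pd_: (round(pd_[1], 9), pd_[0]))
    return pairs[:6]


def build_feature_vector(
    structure: ProteinStructure,
    tess: Tessellation,
    potential: QuadrupletPotential,
    variant: Variant,
    label: str | None = None,
    depth: Mapping[str, str] | None = None,
) -> dict:
    """Assemble the 27-attribute vector (plus bookkeeping) for one variant.

    Returns a dict with the 27 :data:`FEATURE_COLUMNS`, a ``padded`` flag
    (True when the position has fewer than six neighbors), and an
    ``activity`` entry when a U/A label is supplied.
    """
    if label is not None and label not in ("U", "A"):
        raise ValueError("label must be 'U' or 'A'")
    if depth is None:
        depth = classify_depth(tess)
    prof = residual_profile(tess, structure.sequence, potential, variant)
    ep_by_pos = dict(zip(prof.positions, prof.ep))
    neighbors = nearest_six_neighbors(tess, variant.position)
    aa_by_pos = {r.seq_number: r.aa for r in structure.residues}

    row: dict = {
        "position": variant.position,
        "native": variant.native,
        "replacement": variant.replacement,
        "residual_score": prof.residual_score,
    }
    for k in range(6):
        if k < len(neighbors):
            pos, _dist = neighbors[k]
            row[f"ep_n{k + 1}"] = float(ep_by_pos[pos])
            row[f"aa_n{k + 1}"] = aa_by_pos[pos]
            row[f"offset_n{k + 1}"] = pos - variant.position
        else:
            row[f"ep_n{k + 1}"] = 0.0
            row[f"aa_n{k + 1}"] = PAD_AA
            row[f"offset_n{k + 1}"] = 0

    idx = tess.index_of(variant.position)
    incident = tess.incident_simplices(idx)
    if len(incident):
        geos = [tetrahedron_geometry(tess.points[s]) for s in incident]
        row["mean_volume"] = float(np.mean([g.volume for g in geos]))
        row["mean_tetrahedrality"] = float(np.mean([g.tetrahedrality for g in geos]))
    else:
        row["mean_volume"] = 0.0
        row["mean_tetrahedrality"] = 0.0

    row["secondary_structure"] = structure.residue_at(variant.position).ss
    row["depth"] = depth[variant.position]
    row["surface_edges"] = surface_edge_count(tess, variant.position, depth)
    row["padded"] = len(neighbors) < 6
    if label is not None:
        row["activity"] = label
    return row


def enumerate_variants(
    positions_with_native: Sequence[tuple[int, str]],
    substitution_set: Iterable[str],
) -> list[Variant]:
    """All substitutions of the given residues by the given replacement set.

    For each (position, native), one variant per replacement in the set
    with replacement ≠ native — a position whose native residue belongs to
    the set yields one fewer variant.
    """
    subs = list(dict.fromkeys(substitution_set))
    for aa in subs:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid code {aa!r}")
    out = []
    for position, native in positions_with_native:
        for replacement in subs:
            if replacement != native:
                out.append(Variant(position=position, native=native,
                                   replacement=replacement))
    return out


def encode_dataset(
    variants: Sequence[Variant],
    structure: ProteinStructure,
    tess: Tessellation,
    potential: QuadrupletPotential,
    labels: Mapping[Variant, str] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """One feature row per variant, ordered by (position, replacement).

    ``labels`` may be a mapping from Variant to "U"/"A" or a sequence
    aligned with ``variants``. Duplicate variants are an error.
    """
    seen = set()
    for v in variants:
        if v in seen:
            raise ValueError(f"duplicate variant {v}")
        seen.add(v)
    if labels is not None and not isinstance(labels, Mapping):
        labels = dict(zip(variants, labels))
    depth = classify_depth(tess)
    rows = [build_feature_vector(structure, tess, potential, v,
                                 label=None if labels is None else labels[v],
                                 depth=depth)
            for v in variants]
    columns = list(FEATURE_COLUMNS) + ["padded"]
    if labels is not None:
        columns.append("activity")
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["position", "replacement"],
                          kind="mergesort").reset_index(drop=True)


def read_variant_list(path_or_lines) -> list[tuple[Variant, str | None]]:
    """Parse a plain-text variant list.

    Accepts one variant per line, either compact (``E14C`` with an optional
    trailing U/A label) or tab-separated (position, native, replacement
    [, label]). Blank lines and ``#`` comments are ignored.
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = path_or_lines
    else:
        from pathlib import Path

        lines = Path(path_or_lines).read_text().splitlines()
    out: list[tuple[Variant, str | None]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace("\t", " ").split()
        try:
            if len(fields) >= 3 and fields[0].isdigit():
                variant = Variant(position=int(fields[0]), native=fields[1],
                                  replacement=fields[2])
                label = fields[3] if len(fields) > 3 else None
            else:
                variant = Variant.parse(fields[0])
                label = fields[1] if len(fields) > 1 else None
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        if label is not None and label not in ("U", "A"):
            raise ValueError(f"line {lineno}: label must be U or A, got {label!r}")
        out.append((variant, label))
    return out
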