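"""Computational mutagenesis on a fixed tessellation.

A single-residue substitution changes only the amino-acid label at one Cα
vertex; the tessellation is never rebuilt. The substitution therefore
rescores exactly the tetrahedra incident to that vertex, perturbing the
residue environment scores (RES) of the mutated position and its
tessellation neighbors and nothing else. The environmental perturbation
EP_i = q_i,mut − q_i,wt at the mutated position itself is the variant's
residual score, and it equals the total-potential difference
tp_mut − tp_wt identically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .potential import QuadrupletPotential, canonical_key
from .structure_io import AMINO_ACIDS
from .tessellation import Tessellation

logger = logging.getLogger(__name__)

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Variant:
    """A single-residue substitution in author numbering, e.g. E14C."""

    position: int
    native: str
    replacement: str

    def __post_init__(self) -> None:
        for aa in (self.native, self.replacement):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid code {aa!r}")

    @classmethod
    def parse(cls, text: str) -> "Variant":
        m = _VARIANT_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse variant {text!r} (expected e.g. E14C)")
        return cls(native=m.group(1), position=int(m.group(2)),
                   replacement=m.group(3))

    def __str__(self) -> str:
        return f"{self.native}{self.position}{self.replacement}"


@dataclass(frozen=True)
class PotentialProfile:
    """Per-position residue environment scores q_i and the total potential."""

    positions: tuple[int, ...]
    q: np.ndarray
    tp: float


@dataclass(frozen=True)
class ResidualProfile:
    """Per-position EP scores of one variant and its residual score."""

    variant: Variant
    positions: tuple[int, ...]
    ep: np.ndarray
    residual_score: float

    def nonzero_positions(self, tol: float = 0.0) -> list[int]:
        return [p for p, e in zip(self.positions, self.ep) if abs(e) > tol]


@dataclass(frozen=True)
class CMProfile:
    """Comprehensive mutational profile: mean of 19 residual scores per site."""

    positions: tuple[int, ...]
    cmp: np.ndarray


def _check_sequence(tess: Tessellation, sequence: str) -> None:
    if len(sequence) != tess.n_vertices:
        raise ValueError(
            f"sequence length {len(sequence)} does not match "
            f"{tess.n_vertices} tessellation vertices")


def _simplex_scores(tess: Tessellation, sequence: str,
                    potential: QuadrupletPotential) -> np.ndarray:
    return np.array([
        potential.score(canonical_key(sequence[v] for v in s.tolist()))
        for s in tess.simplices])


def total_potential(tess: Tessellation, sequence: str,
                    potential: QuadrupletPotential) -> float:
    """tp = sum of the quadruplet scores of all retained tetrahedra."""
    _check_sequence(tess, sequence)
    return float(_simplex_scores(tess, sequence, potential).sum())


def potential_profile(tess: Tessellation, sequence: str,
                      potential: QuadrupletPotential) -> PotentialProfile:
    """The 3D-1D potential profile: q_i per position, plus tp.

    q_i sums the scores of the tetrahedra sharing position i's Cα as a
    vertex, so Σ_i q_i = 4·tp (each tetrahedron feeds all 4 of its
    vertices). Simplex-free vertices get q = 0.
    """
    _check_sequence(tess, sequence)
    scores = _simplex_scores(tess, sequence, potential)
    q = np.zeros(tess.n_vertices)
    for score, simplex in zip(scores, tess.simplices):
        q[simplex] += score
    return PotentialProfile(positions=tess.positions, q=q,
                            tp=float(scores.sum()))


def _mutate(sequence: str, index: int, replacement: str) -> str:
    return sequence[:index] + replacement + sequence[index + 1:]


def _resolve_variant(tess: Tessellation, sequence: str,
                     variant: Variant) -> int:
    idx = tess.index_of(variant.position)
    if sequence[idx] != variant.native:
        raise ValueError(
            f"native mismatch at position {variant.position}: structure has "
            f"{sequence[idx]}, variant says {variant.native}")
    return idx


def residual_profile(tess: Tessellation, sequence: str,
                     potential: QuadrupletPotential,
                     variant: Variant) -> ResidualProfile:
    """EP profile of one variant: EP_i = q_i,mut − q_i,wt.

    Only tetrahedra incident to the mutated vertex change score, so EP is
    supported on the mutated position and its tessellation neighbors. A
    mutation at a simplex-free vertex yields an all-zero profile.
    """
    _check_sequence(tess, sequence)
    idx = _resolve_variant(tess, sequence, variant)
    mut_seq = _mutate(sequence, idx, variant.replacement)
    ep = np.zeros(tess.n_vertices)
    incident = tess.incident_simplices(idx)
    if len(incident) == 0:
        logger.warning("position %d is simplex-free: all-zero profile",
                       variant.position)
    for simplex in incident:
        verts = simplex.tolist()
        delta = (potential.score(canonical_key(mut_seq[v] for v in verts))
                 - potential.score(canonical_key(sequence[v] for v in verts)))
        ep[simplex] += delta
    return ResidualProfile(variant=variant, positions=tess.positions, ep=ep,
                           residual_score=float(ep[idx]))


def residual_score(tess: Tessellation, sequence: str,
                   potential: QuadrupletPotential, variant: Variant,
                   check_identity: bool = True) -> float:
    """The variant's global perturbation score, EP at the mutated position.

    With ``check_identity`` the score is also recomputed as tp_mut − tp_wt
    from scratch and the two routes are asserted to agree within 1e-9.
    """
    profile = residual_profile(tess, sequence, potential, variant)
    if check_identity:
        idx = tess.index_of(variant.position)
        mut_seq = _mutate(sequence, idx, variant.replacement)
        delta_tp = (total_potential(tess, mut_seq, potential)
                    - total_potential(tess, sequence, potential))
        if abs(delta_tp - profile.residual_score) > 1e-9:
            raise AssertionError(
                f"residual-score routes disagree: profile "
                f"{profile.residual_score!r} vs Δtp {delta_tp!r}")
    return profile.residual_score


def comprehensive_mutational_profile(
    tess: Tessellation, sequence: str,
    potential: QuadrupletPotential,
) -> CMProfile:
    """CMP_i: mean residual score over the 19 non-native replacements at i."""
    _check_sequence(tess, sequence)
    cmp_values = np.zeros(tess.n_vertices)
    for idx in range(tess.n_vertices):
        native = sequence[idx]
        total = 0.0
        for replacement in AMINO_ACIDS:
            if replacement == native:
                continue
            prof = residual_profile(
                tess, sequence, potential,
                Variant(position=tess.positions[idx], native=native,
                        replacement=replacement))
            total += prof.residual_score
        cmp_values[idx] = total / 19.0
    return CMProfile(positions=tess.positions, cmp=cmp_values)
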