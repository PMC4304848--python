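"""Synthetic protein-like inputs for exercising the full pipeline.

Real training corpora are large curated sets of PDB chains; this module
generates stand-ins with the geometric features the tessellation machinery
assumes: Cα traces built as confined self-avoiding random walks with
~3.8 Å consecutive spacing and a 3.5 Å excluded-volume radius, which yield
tessellation edge-length spectra mostly below the 12 Å cutoff. Labeled
variant datasets are produced by thresholding residual scores (class A
below the threshold) and optionally flipping labels with a noise
probability, emulating an experimental activity screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutagenesis import Variant, residual_profile
from .potential import QuadrupletPotential
from .structure_io import AMINO_ACIDS, ProteinStructure, Residue
from .tessellation import DEFAULT_CUTOFF, Tessellation, tessellate_structure


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic Cα-trace generator."""

    n_residues: int = 100
    step: float = 3.8             # Å; consecutive Cα spacing, ±1% jitter
    min_separation: float = 3.5   # Å; excluded-volume radius
    composition: dict | None = None  # aa -> probability; None = uniform
    seed: int = 0
    chain_id: str = "A"


def _composition_arrays(composition: dict | None) -> tuple[list[str], np.ndarray]:
    if composition is None:
        letters = list(AMINO_ACIDS)
        probs = np.full(20, 0.05)
    else:
        letters = list(composition)
        probs = np.array([composition[aa] for aa in letters], dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("composition must be a probability distribution")
        for aa in letters:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid code {aa!r}")
    return letters, probs


def generate_structure(spec: SyntheticSpec) -> ProteinStructure:
    """A confined self-avoiding Cα walk with a random sequence.

    Consecutive residues sit step ± 1% apart, all pairs at least
    ``min_separation`` apart, and the walk is kept inside a sphere whose
    radius scales as n^(1/3) so the trace is globular (protein-like
    density) rather than an extended coil. Secondary structure is labeled
    C throughout. Deterministic for a fixed seed.
    """
    if spec.n_residues < 4:
        raise ValueError("at least 4 residues are required")
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition_arrays(spec.composition)
    # 3.0 Å · n^(1/3) encloses ~113 Å³ per residue, close to the packing
    # density of globular proteins, so deeper residues end up buried
    confine_radius = max(2.5 * spec.step, 3.0 * spec.n_residues ** (1 / 3))
    for _restart in range(50):
        coords = [np.zeros(3)]
        failed = False
        while len(coords) < spec.n_residues:
            placed = False
            for _attempt in range(300):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                step = spec.step * rng.uniform(0.99, 1.01)
                candidate = coords[-1] + step * direction
                if np.linalg.norm(candidate) > confine_radius:
                    continue
                prev = np.asarray(coords[:-1])
                if len(prev) and (np.linalg.norm(prev - candidate, axis=1)
                                  < spec.min_separation).any():
                    continue
                coords.append(candidate)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            seq = rng.choice(letters, size=spec.n_residues, p=probs)
            residues = tuple(
                Residue(seq_number=i + 1, aa=str(seq[i]),
                        ca_xyz=tuple(coords[i]), ss="C")
                for i in range(spec.n_residues))
            return ProteinStructure(chain_id=spec.chain_id, residues=residues)
    raise RuntimeError("self-avoiding walk failed after 50 restarts")


def generate_corpus(n_structures: int, size_range: tuple[int, int] = (60, 120),
                    composition: dict | None = None,
                    seed: int = 0) -> list[ProteinStructure]:
    """A list of independent synthetic structures (training-corpus stand-in)."""
    if n_structures < 1:
        raise ValueError("n_structures must be ≥ 1")
    lo, hi = size_range
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_structures):
        n = int(rng.integers(lo, hi + 1))
        out.append(generate_structure(SyntheticSpec(
            n_residues=n, composition=composition,
            seed=int(rng.integers(0, 2**31 - 1)))))
    return out


def corpus_tessellations(corpus, cutoff: float = DEFAULT_CUTOFF
                         ) -> list[tuple[Tessellation, str]]:
    """(filtered tessellation, sequence) pairs ready for potential training."""
    return [(tessellate_structure(s, cutoff=cutoff), s.sequence)
            for s in corpus]


def generate_variant_dataset(
    structure: ProteinStructure,
    tess: Tessellation,
    potential: QuadrupletPotential,
    n_variants: int,
    tau: float | None = None,
    eps: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled single-residue variants for classifier training.

    Variants are drawn uniformly without replacement from all
    (position, replacement ≠ native) pairs. Each is labeled A when its
    residual score falls below the threshold ``tau`` (default: the median
    residual score of the drawn variants, which balances the classes) and
    U otherwise; labels are then flipped independently with probability
    ``eps``. Returns a frame with columns position, native, replacement,
    residual_score, activity.
    """
    if not 0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    seq = structure.sequence
    all_pairs = [(r.seq_number, r.aa, repl)
                 for r in structure.residues
                 for repl in AMINO_ACIDS if repl != r.aa]
    if n_variants > len(all_pairs):
        raise ValueError(f"n_variants exceeds the {len(all_pairs)} possible "
                         "single-residue variants")
    chosen = rng.choice(len(all_pairs), size=n_variants, replace=False)
    rows = []
    for idx in chosen:
        pos, native, repl = all_pairs[idx]
        variant = Variant(position=pos, native=native, replacement=repl)
        score = residual_profile(tess, seq, potential, variant).residual_score
        rows.append({"position": pos, "native": native, "replacement": repl,
                     "residual_score": score})
    df = pd.DataFrame(rows)
    if tau is None:
        tau = float(df["residual_score"].median())
    labels = np.where(df["residual_score"] < tau, "A", "U")
    flips = rng.random(n_variants) < eps
    labels = np.where(flips, np.where(labels == "A", "U", "A"), labels)
    df["activity"] = labels
    df.attrs["tau"] = tau
    df.attrs["eps"] = eps
    df.attrs["seed"] = seed
    return df
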