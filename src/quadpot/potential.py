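"""Four-body statistical potential over residue quadruplets.

Each tetrahedron of a filtered tessellation identifies an unordered
quadruplet of residues (repeats allowed), written as a canonical key in
ascending alphabetical order, e.g. CCDH. Over a training corpus the
observed relative frequency f of each of the C(23, 4) = 8,855 quadruplet
types is compared with its multinomial chance expectation

    p = 4! / (t_1! … t_20!) · Π a_n^{t_n},

where a_n is the corpus amino-acid composition and t_n counts repeats of
type n in the quadruplet (Σ t_n = 4). The inverted-Boltzmann log-likelihood
ratio of f to p is the quadruplet's interaction score; the 8,855 scores
together form the potential.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure_io import AMINO_ACIDS
from .tessellation import Tessellation

N_QUADRUPLETS = 8855  # C(20 + 4 - 1, 4)

#: sign conventions for the log-likelihood score
#: "empirical": s = +log(f/p) — overrepresented quadruplets score positive,
#:   so destabilizing replacements produce negative residual scores.
#: "paper":     s = −log(f/p), the printed inverted-Boltzmann form.
SIGN_CONVENTIONS = ("empirical", "paper")


def canonical_key(residues: Iterable[str]) -> str:
    """Canonical quadruplet key: the 4 letters sorted ascending.

    All 24 permutations of the same residues map to one key, e.g.
    (H, D, C, C) → "CCDH".
    """
    letters = list(residues)
    if len(letters) != 4:
        raise ValueError("a quadruplet has exactly 4 residues")
    for aa in letters:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid code {aa!r}")
    return "".join(sorted(letters))


def enumerate_quadruplets(alphabet_size: int = 20, subset_size: int = 4,
                          alphabet: str | None = None) -> list[str]:
    """All C(K+r−1, r) multiset keys over the first K alphabet letters."""
    if alphabet is None:
        alphabet = AMINO_ACIDS
    if not 1 <= alphabet_size <= len(alphabet):
        raise ValueError("alphabet_size out of range")
    letters = alphabet[:alphabet_size]
    return ["".join(c) for c in combinations_with_replacement(letters, subset_size)]


def observed_frequencies(
    corpus: Iterable[tuple[Tessellation, str]],
) -> tuple[Counter, dict[str, float], int]:
    """Count retained tetrahedra per canonical quadruplet over a corpus.

    ``corpus`` yields (filtered tessellation, sequence) pairs where
    ``sequence[i]`` is the residue at vertex index ``i``. Returns
    (counts, relative frequencies, total tetrahedra).
    """
    counts: Counter = Counter()
    total = 0
    n_items = 0
    for tess, sequence in corpus:
        n_items += 1
        if len(sequence) != tess.n_vertices:
            raise ValueError("sequence length does not match vertex count")
        for simplex in tess.simplices:
            counts[canonical_key(sequence[v] for v in simplex.tolist())] += 1
            total += 1
    if n_items == 0:
        raise ValueError("empty corpus")
    f = {k: c / total for k, c in counts.items()} if total else {}
    return counts, f, total


def residue_composition(sequences: Iterable[str]) -> dict[str, float]:
    """Proportion a_n of each amino-acid type over pooled corpus sequences."""
    counts: Counter = Counter()
    for seq in sequences:
        counts.update(seq)
    bad = set(counts) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid letters in sequences: {sorted(bad)}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no residues in sequences")
    return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def multinomial_reference(key: str, composition: Mapping[str, float]) -> float:
    """Chance probability of a quadruplet under the multinomial model."""
    t = Counter(key)
    coeff = math.factorial(4)
    prob = 1.0
    for aa, t_n in t.items():
        coeff //= math.factorial(t_n)
        prob *= composition.get(aa, 0.0) ** t_n
    return coeff * prob


def log_likelihood_score(f: float, p: float, log_base: float = 10.0,
                         sign: str = "empirical") -> float:
    """Score one quadruplet from its observed and reference frequencies."""
    if sign not in SIGN_CONVENTIONS:
        raise ValueError(f"sign must be one of {SIGN_CONVENTIONS}")
    if p <= 0:
        raise ValueError("reference probability must be positive "
                         "(composition lacks a residue used in the quadruplet)")
    if f <= 0:
        raise ValueError("observed frequency must be positive; apply a "
                         "pseudo-count before scoring")
    s = math.log(f / p, log_base)
    return s if sign == "empirical" else -s


@dataclass(frozen=True)
class QuadrupletPotential:
    """The trained potential: one record per canonical quadruplet key."""

    counts: dict[str, int]
    f: dict[str, float]
    p: dict[str, float]
    s: dict[str, float]
    composition: dict[str, float]
    metadata: dict[str, object] = field(default_factory=dict)

    def score(self, key_or_residues) -> float:
        key = key_or_residues if isinstance(key_or_residues, str) \
            else canonical_key(key_or_residues)
        try:
            return self.s[key]
        except KeyError:
            raise KeyError(f"quadruplet {key!r} not in potential") from None

    def scaled(self, factor: float) -> "QuadrupletPotential":
        """Potential with every score multiplied by ``factor``."""
        return QuadrupletPotential(
            counts=dict(self.counts), f=dict(self.f), p=dict(self.p),
            s={k: v * factor for k, v in self.s.items()},
            composition=dict(self.composition),
            metadata={**self.metadata, "scaled_by": factor})

    def __len__(self) -> int:
        return len(self.s)


def train_potential(
    corpus: Sequence[tuple[Tessellation, str]],
    pseudocount: float = 1.0,
    log_base: float = 10.0,
    sign: str = "empirical",
) -> QuadrupletPotential:
    """Derive the four-body potential from a corpus of filtered tessellations.

    A pseudo-count is added to every quadruplet's raw count before computing
    f, so unobserved quadruplets receive a finite score instead of ±∞. The
    composition a_n is taken over all residues of the corpus chains, not
    only tessellation-retained vertices.
    """
    corpus = list(corpus)
    counts, _, total = observed_frequencies(corpus)
    composition = residue_composition(seq for _, seq in corpus)
    keys = enumerate_quadruplets()
    denom = total + pseudocount * len(keys)
    f = {k: (counts.get(k, 0) + pseudocount) / denom for k in keys}
    p = {k: multinomial_reference(k, composition) for k in keys}
    s = {k: log_likelihood_score(f[k], p[k], log_base=log_base, sign=sign)
         for k in keys}
    cutoffs = {t.cutoff for t, _ in corpus}
    return QuadrupletPotential(
        counts={k: counts.get(k, 0) for k in keys}, f=f, p=p, s=s,
        composition=composition,
        metadata={"corpus_size": len(corpus),
                  "total_tetrahedra": total,
                  "cutoff": cutoffs.pop() if len(cutoffs) == 1 else "mixed",
                  "log_base": log_base,
                  "sign": sign,
                  "pseudocount": pseudocount})


def write_potential(potential: QuadrupletPotential, path: str | Path) -> Path:
    """Serialize a potential to TSV with ``#`` metadata header lines."""
    path = Path(path)
    lines = []
    for k, v in potential.metadata.items():
        lines.append(f"# {k}={v}")
    for aa in AMINO_ACIDS:
        lines.append(f"# a_{aa}={potential.composition[aa]!r}")
    lines.append("key\tcount\tf\tp\ts")
    for key in sorted(potential.s):
        lines.append(f"{key}\t{potential.counts.get(key, 0)}\t"
                     f"{potential.f[key]!r}\t{potential.p[key]!r}\t"
                     f"{potential.s[key]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_potential(path: str | Path) -> QuadrupletPotential:
    """Load a TSV potential table written by :func:`write_potential`.

    Also accepts externally supplied tables with the same 5-column schema.
    """
    path = Path(path)
    metadata: dict[str, object] = {}
    composition: dict[str, float] = {}
    counts, f, p, s = {}, {}, {}, {}
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                k = k.strip()
                if k.startswith("a_") and len(k) == 3:
                    composition[k[2:]] = float(v)
                else:
                    metadata[k] = _parse_meta(v.strip())
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[:5] != ["key", "count", "f", "p", "s"]:
                raise ValueError(f"line {lineno}: unexpected header {line!r}")
            header_seen = True
            continue
        if len(fields) != 5:
            raise ValueError(f"line {lineno}: expected 5 fields, got {len(fields)}")
        key = fields[0]
        if len(key) != 4 or key != "".join(sorted(key)):
            raise ValueError(f"line {lineno}: invalid quadruplet key {key!r}")
        try:
            counts[key] = int(fields[1])
            f[key] = float(fields[2])
            p[key] = float(fields[3])
            s[key] = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    if not header_seen:
        raise ValueError("no header line found")
    return QuadrupletPotential(counts=counts, f=f, p=p, s=s,
                               composition=composition, metadata=metadata)
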