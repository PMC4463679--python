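"""Synthetic labeled protein-pair datasets with tunable class separation.

Proteins are i.i.d. residue strings drawn from one of two emission
distributions over the 20 standard amino acids:

    D1 = (1 - s) * uniform + s * q1        (interacting class)
    D2 = (1 - s) * uniform + s * q2        (non-interacting class)

where q1 and q2 are uniform over two disjoint residue sets that fall into
different reduced-alphabet groups, so the total-variation distance between
D1 and D2 equals the separation s in [0, 1].  Interacting pairs draw both
proteins from D1; non-interacting pairs draw both from D2 (or one from
each with ``negative_mode="mixed"``).  At s = 0 the two classes are
statistically identical; at s near 1 their reduced compositions barely
overlap.  Output is ordinary FASTA + pair-list data, fully reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import STANDARD_RESIDUES
from .errors import DataValidationError
from .io_formats import ProteinRecord

#: Residues enriched in the interacting class: hydrophobic/aromatic,
#: a single CP(5) group.
D1_ENRICHED = "IVFYW"
#: Residues enriched in the non-interacting class: small/polar,
#: a different CP(5) group.
D2_ENRICHED = "NDHSTC"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    Attributes
    ----------
    n_pairs : int
        Pairs per class (total 2 * n_pairs samples).
    length_range : (int, int)
        Inclusive protein length bounds; the default starts at the
        standard 50-residue filter floor.
    separation : float
        Total-variation distance between the two emission distributions,
        in [0, 1].
    seed : int
        Seed for all randomness.
    negative_mode : {"d2", "mixed"}
        Non-interacting pairs draw both proteins from D2, or one from D1
        and one from D2.
    """

    n_pairs: int = 200
    length_range: tuple[int, int] = (50, 300)
    separation: float = 0.9
    seed: int = 0
    negative_mode: str = "d2"


def class_distributions(separation: float) -> tuple[np.ndarray, np.ndarray]:
    """Emission distributions (D1, D2) over the 20 standard residues.

    The total-variation distance between the returned distributions equals
    ``separation`` exactly (the enriched sets are disjoint).
    """
    if not 0.0 <= separation <= 1.0:
        raise DataValidationError(
            f"separation must be in [0, 1], got {separation}"
        )
    n = len(STANDARD_RESIDUES)
    uniform = np.full(n, 1.0 / n)
    q1 = np.zeros(n)
    q2 = np.zeros(n)
    for res in D1_ENRICHED:
        q1[STANDARD_RESIDUES.index(res)] = 1.0 / len(D1_ENRICHED)
    for res in D2_ENRICHED:
        q2[STANDARD_RESIDUES.index(res)] = 1.0 / len(D2_ENRICHED)
    d1 = (1.0 - separation) * uniform + separation * q1
    d2 = (1.0 - separation) * uniform + separation * q2
    for d in (d1, d2):
        if d.sum() <= 0:
            raise DataValidationError("degenerate emission distribution")
    return d1 / d1.sum(), d2 / d2.sum()


def _draw_protein(
    rng: np.random.Generator, dist: np.ndarray, length_range: tuple[int, int]
) -> str:
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(list(STANDARD_RESIDUES), size=length, p=dist)
    return "".join(letters)


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[tuple[str, str, int]]]:
    """Generate a labeled synthetic dataset.

    Returns
    -------
    records : list of ProteinRecord
        Two fresh proteins per pair (4 * n_pairs proteins total).
    pairs : list of (id_a, id_b, label)
        n_pairs interacting (label 1) followed by n_pairs non-interacting
        (label 0).
    """
    if spec.n_pairs < 1:
        raise DataValidationError(f"n_pairs must be >= 1, got {spec.n_pairs}")
    lo, hi = spec.length_range
    if lo < 1 or hi < lo:
        raise DataValidationError(f"bad length range {spec.length_range}")
    if spec.negative_mode not in ("d2", "mixed"):
        raise DataValidationError(
            f"negative_mode must be 'd2' or 'mixed', got {spec.negative_mode!r}"
        )
    d1, d2 = class_distributions(spec.separation)
    rng = np.random.default_rng(spec.seed)

    records: list[ProteinRecord] = []
    pairs: list[tuple[str, str, int]] = []
    for i in range(spec.n_pairs):
        id_a, id_b = f"POS{i:04d}_A", f"POS{i:04d}_B"
        records.append(ProteinRecord(id_a, _draw_protein(rng, d1, spec.length_range)))
        records.append(ProteinRecord(id_b, _draw_protein(rng, d1, spec.length_range)))
        pairs.append((id_a, id_b, 1))
    for i in range(spec.n_pairs):
        id_a, id_b = f"NEG{i:04d}_A", f"NEG{i:04d}_B"
        dist_a = d1 if spec.negative_mode == "mixed" else d2
        records.append(ProteinRecord(id_a, _draw_protein(rng, dist_a, spec.length_range)))
        records.append(ProteinRecord(id_b, _draw_protein(rng, d2, spec.length_range)))
        pairs.append((id_a, id_b, 0))
    return records, pairs
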