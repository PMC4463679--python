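"""n-peptide composition features over a reduced alphabet.

A protein of reduced length L' yields a vector of normalized frequencies of
all length-n windows over the k-letter reduced alphabet: dimension k^n, the
entry for the window (g_1, ..., g_n) sitting at the row-major index
sum_j g_j * k^(n-j).  Counts are divided by the number of windows,
L' - n + 1, so the vector sums to 1.

A protein pair becomes one sample by concatenating the two per-protein
vectors (``combine="concat"``, the default) or by the order-free
symmetrization [a+b ; |a-b|] (``combine="sym"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ClusterProfile, reduce_sequence
from .errors import DataValidationError, SequenceError

PAIR_COMBINERS = ("concat", "sym")


def feature_dimension(profile: ClusterProfile, n: int) -> int:
    """Dimension k^n of the n-peptide composition vector for this profile."""
    if n < 1:
        raise ValueError(f"peptide length n must be >= 1, got {n}")
    return profile.k ** n


@dataclass(frozen=True)
class CompositionVector:
    """Normalized n-peptide frequency vector for one protein."""

    values: np.ndarray
    profile_name: str
    n: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )


def npeptide_composition(
    seq: str,
    profile: ClusterProfile,
    n: int,
    source_id: str = "",
    ambiguous: str = "drop",
) -> CompositionVector:
    """Compute the n-peptide composition of ``seq`` over ``profile``.

    Parameters
    ----------
    seq : str
        Amino-acid sequence (one-letter codes; ambiguity codes handled per
        ``ambiguous``, see :func:`ppisparse.alphabet.reduce_sequence`).
    n : int
        Peptide window length; 1 (composition), 2 (dipeptide) or 3
        (tripeptide) are supported.

    Raises
    ------
    SequenceError
        If the reduced sequence is shorter than ``n``.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"peptide length n must be 1, 2 or 3, got {n}")
    reduced = reduce_sequence(seq, profile, ambiguous=ambiguous)
    if reduced.size < n:
        ident = f" ({source_id})" if source_id else ""
        raise SequenceError(
            f"sequence{ident} has reduced length {reduced.size} < n={n}"
        )
    k = profile.k
    dim = k ** n
    # row-major window index: sum_j g_j * k^(n-1-j)
    idx = reduced[: reduced.size - n + 1].copy()
    for j in range(1, n):
        idx = idx * k + reduced[j : reduced.size - n + 1 + j]
    counts = np.bincount(idx, minlength=dim).astype(np.float64)
    values = counts / (reduced.size - n + 1)
    return CompositionVector(
        values=values, profile_name=profile.name, n=n, source_id=source_id
    )


def pair_features(
    a: CompositionVector, b: CompositionVector, combine: str = "concat"
) -> np.ndarray:
    """Assemble one pair feature vector from two per-protein vectors.

    ``"concat"`` gives the ordered concatenation [a ; b] of length 2*k^n;
    ``"sym"`` gives the order-free [a+b ; |a-b|] of the same length.
    """
    if a.profile_name != b.profile_name or a.n != b.n:
        raise DataValidationError(
            "cannot pair features from different encodings: "
            f"({a.profile_name}, n={a.n}) vs ({b.profile_name}, n={b.n})"
        )
    if combine == "concat":
        return np.concatenate([a.values, b.values])
    if combine == "sym":
        return np.concatenate([a.values + b.values, np.abs(a.values - b.values)])
    raise ValueError(f"unknown pair combiner {combine!r}; use one of {PAIR_COMBINERS}")


@dataclass(frozen=True)
class PairSample:
    """One labeled protein pair: concatenated features plus a 0/1 label."""

    features: np.ndarray
    label: int
    id_a: str
    id_b: str


def cell_names(profile: ClusterProfile, n: int) -> list[str]:
    """Header names for the k^n composition cells, 1-based group numbers.

    E.g. for CP(8), n=3 the cell for groups (0, 4, 1) is ``"CP8_n3_g1g5g2"``.
    """
    short = profile.name.replace("(", "").replace(")", "")
    k = profile.k
    names = []
    for flat in range(k ** n):
        digits = []
        rem = flat
        for j in range(n - 1, -1, -1):
            digits.append(rem // k ** j + 1)
            rem %= k ** j
        names.append(f"{short}_n{n}_" + "".join(f"g{d}" for d in digits))
    return names


def build_pair_samples(
    sequences: Mapping[str, str],
    pairs: Iterable[tuple[str, str, int]],
    profile: ClusterProfile,
    n: int,
    combine: str = "concat",
    ambiguous: str = "drop",
) -> list[PairSample]:
    """Featurize labeled (id_a, id_b, label) pairs against a sequence map.

    Each protein is encoded once and reused across the pairs it appears in.
    """
    cache: dict[str, CompositionVector] = {}

    def vec(pid: str) -> CompositionVector:
        if pid not in cache:
            if pid not in sequences:
                raise DataValidationError(f"pair references unknown protein id {pid!r}")
            cache[pid] = npeptide_composition(
                sequences[pid], profile, n, source_id=pid, ambiguous=ambiguous
            )
        return cache[pid]

    samples = []
    for id_a, id_b, label in pairs:
        feats = pair_features(vec(id_a), vec(id_b), combine=combine)
        samples.append(PairSample(features=feats, label=int(label), id_a=id_a, id_b=id_b))
    return samples


def samples_to_matrix(samples: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair samples into a design matrix X (n_samples, d) and labels y."""
    if not samples:
        raise DataValidationError("no pair samples to stack")
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


def samples_to_frame(
    samples: Sequence[PairSample], profile: ClusterProfile, n: int, combine: str = "concat"
) -> pd.DataFrame:
    """Tabular view of pair samples: id_a, id_b, label, then feature cells.

    Column names carry the profile, n, and the 1-based group indices of each
    cell, prefixed ``a_``/``b_`` for the two concatenated halves (or
    ``sum_``/``absdiff_`` for the symmetrized combiner).
    """
    X, y = samples_to_matrix(samples)
    base = cell_names(profile, n)
    prefixes = ("a_", "b_") if combine == "concat" else ("sum_", "absdiff_")
    cols = [prefixes[0] + c for c in base] + [prefixes[1] + c for c in base]
    if X.shape[1] != len(cols):
        raise DataValidationError(
            f"feature width {X.shape[1]} does not match {profile.name}, n={n} "
            f"(expected {len(cols)})"
        )
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", y)
    df.insert(0, "id_b", [s.id_b for s in samples])
    df.insert(0, "id_a", [s.id_a for s in samples])
    return df
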