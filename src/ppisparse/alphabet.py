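"""Reduced amino acid alphabets (RAAA) derived from the protein blocks method.

A *cluster profile* partitions the 20 standard amino acids into k ordered
groups; a sequence is rewritten over group indices before any composition
counting.  Five published profiles, CP(13) down to CP(5), are shipped as
built-ins; custom profiles can be parsed from a dash-separated string such
as ``"G-IVFYW-ALMEQRK-P-NDHSTC"``.

Group indices are 0-based internally; report output uses 1-based numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ProfileError, SequenceError

#: The 20 standard one-letter amino acid codes, in alphabetical order.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes tolerated under the "drop" policy.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BZXUOJ*")


@dataclass(frozen=True)
class ClusterProfile:
    """An ordered partition of the 20 standard residues into k groups.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"CP(8)"``.
    groups : tuple of str
        Residue strings, one per group, in the left-to-right order of the
        dash-separated specification.
    """

    name: str
    groups: tuple[str, ...]
    _residue_to_group: dict[str, int] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        mapping: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            for res in group:
                mapping[res] = gi
        object.__setattr__(self, "_residue_to_group", mapping)

    @property
    def k(self) -> int:
        """Number of groups (the reduced alphabet size)."""
        return len(self.groups)

    @property
    def spec_string(self) -> str:
        """Dash-separated serialization, e.g. ``"G-IVFYW-ALMEQRK-P-NDHSTC"``."""
        return "-".join(self.groups)

    def group_of(self, residue: str) -> int:
        """0-based group index of a standard residue."""
        try:
            return self._residue_to_group[residue]
        except KeyError:
            raise SequenceError(
                f"residue {residue!r} is not covered by profile {self.name}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._residue_to_group


def parse_profile(name: str, spec: str) -> ClusterProfile:
    """Parse and validate a dash-separated cluster-profile specification.

    The groups must be non-empty, pairwise disjoint, and cover the 20
    standard residues exactly.

    Raises
    ------
    ProfileError
        Naming any missing, duplicated, or non-standard residue.
    """
    tokens = spec.strip().upper().split("-")
    if any(tok == "" for tok in tokens):
        raise ProfileError(f"profile {name!r}: empty group in spec {spec!r}")

    seen: set[str] = set()
    duplicated: list[str] = []
    nonstandard: list[str] = []
    for tok in tokens:
        for res in tok:
            if res not in STANDARD_RESIDUES:
                nonstandard.append(res)
            elif res in seen:
                duplicated.append(res)
            else:
                seen.add(res)
    missing = sorted(set(STANDARD_RESIDUES) - seen)

    problems = []
    if nonstandard:
        problems.append(f"non-standard residue(s) {sorted(set(nonstandard))}")
    if duplicated:
        problems.append(f"duplicated residue(s) {sorted(set(duplicated))}")
    if missing:
        problems.append(f"{len(missing)} missing residue(s) {missing}")
    if problems:
        raise ProfileError(f"profile {name!r}: " + "; ".join(problems))

    return ClusterProfile(name=name, groups=tuple(tokens))


# Published protein-blocks cluster profiles.  The integer in the name is the
# number of groups; parse_profile validates the partition on import.
_BUILTIN_SPECS: dict[str, str] = {
    "CP(13)": "G-IV-FYW-A-L-M-E-QRK-P-ND-HS-T-C",
    "CP(11)": "G-IV-FYW-A-LM-EQRK-P-ND-HS-T-C",
    "CP(9)": "G-IV-FYW-ALM-EQRK-P-ND-HS-TC",
    "CP(8)": "G-IV-FYW-ALM-EQRK-P-ND-HSTC",
    "CP(5)": "G-IVFYW-ALMEQRK-P-NDHSTC",
}

BUILTIN_PROFILES: dict[str, ClusterProfile] = {
    name: parse_profile(name, spec) for name, spec in _BUILTIN_SPECS.items()
}

for _name, _prof in BUILTIN_PROFILES.items():
    assert _prof.k == int(_name[3:-1]), f"builtin {_name} has k={_prof.k}"


def get_profile(name: str) -> ClusterProfile:
    """Look up a built-in profile by name (``"CP(13)"`` ... ``"CP(5)"``).

    Accepts the bare alias ``"CP8"`` as well as ``"CP(8)"``.
    """
    key = name.strip().upper()
    if key not in BUILTIN_PROFILES and key.startswith("CP") and "(" not in key:
        key = f"CP({key[2:]})"
    try:
        return BUILTIN_PROFILES[key]
    except KeyError:
        known = ", ".join(BUILTIN_PROFILES)
        raise ProfileError(f"unknown profile {name!r}; built-ins: {known}") from None


def identity_profile() -> ClusterProfile:
    """The trivial 20-group alphabet: every residue its own group."""
    return parse_profile("identity", "-".join(STANDARD_RESIDUES))


def load_profile(path: str | Path, name: str | None = None) -> ClusterProfile:
    """Load a custom profile from a one-line text file with the dash spec."""
    path = Path(path)
    text = path.read_text().strip()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) != 1:
        raise ProfileError(
            f"{path}: expected a single dash-separated spec line, got {len(lines)}"
        )
    return parse_profile(name or path.stem, lines[0])


def reduce_sequence(
    seq: str, profile: ClusterProfile, ambiguous: str = "drop"
) -> np.ndarray:
    """Map a residue string to an array of 0-based group indices.

    Input is uppercased first.  Ambiguity codes (B, Z, X, U, O, J and ``*``)
    are handled per ``ambiguous``: ``"drop"`` removes them before mapping,
    ``"error"`` raises.  Any other unmappable character always raises,
    naming the position and residue.
    """
    if not seq:
        raise SequenceError("empty sequence")
    if ambiguous not in ("drop", "error"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")

    out: list[int] = []
    for pos, res in enumerate(seq.upper()):
        if res in profile:
            out.append(profile.group_of(res))
        elif res in AMBIGUOUS_RESIDUES and ambiguous == "drop":
            continue
        else:
            raise SequenceError(
                f"unmappable residue {res!r} at position {pos + 1}"
            )
    return np.asarray(out, dtype=np.int64)
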