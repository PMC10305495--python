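"""Set similarity between drug neighborhoods and drug structures.

Two drug networks are compared by the Jaccard index of their first-neighbor
protein sets, summarised by the contingency counts M11 (shared), M10
(unique to A), and M01 (unique to B), with J = M11/(M11+M10+M01) and
Jaccard distance dJ = 1 − J.  Drug structures are compared by the Tanimoto
coefficient of path-based fingerprint feature sets — mathematically the
same coefficient applied to feature ids instead of protein accessions.

A zero denominator (both sets empty) is treated as *undefined* rather than
0: a silent zero would hide upstream input errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .exceptions import (
    DomainError,
    SnapshotFormatError,
    UndefinedResultError,
    UsageError,
)
from .io_core import ProteinID

#: Supported fingerprint schemes.  ``path_based`` enumerates all linear
#: atom–bond paths of length 1..7 and hashes each to an integer feature id.
FINGERPRINT_SCHEMES = ("path_based",)

_PATH_MIN, _PATH_MAX = 1, 7


@dataclass(frozen=True)
class NeighborComparison:
    """One row of a neighbor-set comparison table.

    Invariants: m11 + m10 = |A|, m11 + m01 = |B|,
    jaccard = m11/(m11+m10+m01), jaccard_distance = 1 − jaccard.
    """

    label_a: str
    label_b: str
    m11: int
    m10: int
    m01: int
    jaccard: float
    jaccard_distance: float

    def formatted(self, decimals: int = 6) -> tuple[str, ...]:
        """Row rendered for reports, indices printed to ``decimals``."""
        return (
            self.label_a,
            self.label_b,
            str(self.m11),
            str(self.m10),
            str(self.m01),
            f"{round(self.jaccard, decimals):g}",
            f"{round(self.jaccard_distance, decimals):g}",
        )


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    scheme: str
    molecule_id: str | None = None


def jaccard_from_counts(m11: int, m10: int, m01: int) -> tuple[float, float]:
    """(J, dJ) from shared/unique counts; all-zero counts are undefined."""
    for name, v in (("m11", m11), ("m10", m10), ("m01", m01)):
        if v < 0 or v != int(v):
            raise DomainError(f"{name} must be a non-negative integer, got {v!r}")
    total = m11 + m10 + m01
    if total == 0:
        raise UndefinedResultError("Jaccard index undefined for all-zero counts")
    j = m11 / total
    return j, 1.0 - j


def neighbor_jaccard(
    neighbors_a: set[ProteinID],
    neighbors_b: set[ProteinID],
    label_a: str = "A",
    label_b: str = "B",
    empty_as_zero: bool = False,
) -> NeighborComparison:
    """Compare two first-neighbor sets.

    Symmetric up to swapping the labels and the M10/M01 counts.  Two empty
    sets are undefined unless ``empty_as_zero`` explicitly requests the
    J = 0 convention.
    """
    a, b = set(neighbors_a), set(neighbors_b)
    m11 = len(a & b)
    m10 = len(a - b)
    m01 = len(b - a)
    if m11 + m10 + m01 == 0:
        if not empty_as_zero:
            raise UndefinedResultError(
                f"both neighbor sets empty for {label_a!r} vs {label_b!r}"
            )
        j, dj = 0.0, 1.0
    else:
        j, dj = jaccard_from_counts(m11, m10, m01)
    return NeighborComparison(label_a, label_b, m11, m10, m01, j, dj)


def fingerprint(
    smiles: str, scheme: str = "path_based", molecule_id: str | None = None
) -> Fingerprint:
    """Deterministic feature-id set for a molecule given as SMILES.

    The ``path_based`` scheme hashes every linear atom–bond path of length
    1..7 to an integer id (unfolded, so no bit collisions from folding);
    identical SMILES always yield identical bit sets.
    """
    if scheme not in FINGERPRINT_SCHEMES:
        raise UsageError(f"unknown fingerprint scheme {scheme!r}")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SnapshotFormatError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=_PATH_MIN, maxPath=_PATH_MAX, branchedPaths=False
    )
    bits = frozenset(int(b) for b in gen.GetSparseFingerprint(mol).GetOnBits())
    return Fingerprint(bits=bits, scheme=scheme, molecule_id=molecule_id)


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """|A∩B| / |A∪B| over fingerprint feature sets; 1 means feature
    identity.  Requires both fingerprints to use the same scheme."""
    if fa.scheme != fb.scheme:
        raise UsageError(
            f"fingerprint scheme mismatch: {fa.scheme!r} vs {fb.scheme!r}"
        )
    union = fa.bits | fb.bits
    if not union:
        raise UndefinedResultError("Tanimoto undefined for two empty fingerprints")
    return len(fa.bits & fb.bits) / len(union)


def smiles_tanimoto(smiles_a: str, smiles_b: str,
                    scheme: str = "path_based") -> float:
    """Convenience wrapper: fingerprint both SMILES and compare."""
    return tanimoto(fingerprint(smiles_a, scheme), fingerprint(smiles_b, scheme))


def load_reference_comparisons() -> list[dict]:
    """The shipped reference table of published first-neighbor overlap
    counts for the sartan / Paxlovid / perphenazine drug networks.

    Each row carries the raw counts plus the originally printed index and
    distance values (strings, at their printed precision) so callers can
    recompute the indices from the counts and check agreement.
    """
    ref = resources.files("offtargetnet.data") / "reference_neighbor_counts.tsv"
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for raw in reader:
            rows.append(
                {
                    "label_a": raw["drug_a"],
                    "label_b": raw["drug_b"],
                    "m11": int(raw["m11"]),
                    "m10": int(raw["m10"]),
                    "m01": int(raw["m01"]),
                    "printed_jaccard": raw["jaccard"],
                    "printed_jaccard_distance": raw["jaccard_distance"],
                }
            )
    return rows
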