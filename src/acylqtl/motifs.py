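"""BAHD acyltransferase motif filtering and segregation goodness-of-fit.

BAHD-superfamily acyltransferases carry the catalytic HXXXD motif and the
structural DFGWG motif; anthocyanin acyltransferases additionally share an
AAT-specific C-terminal motif whose functional-malonyltransferase form is
xY[F/L]GNC (any residue, Tyr, Phe-or-Leu, Gly, Asn, Cys).  Candidate protein
sequences are filtered on the presence of that third motif.

Also here: the Pearson chi-square goodness-of-fit test against an expected
segregation ratio (e.g. 1:1 for a heterozygous-knockout cross).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import InvalidExpectationError, InvalidInputError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifSpec:
    """An ordered residue pattern: fixed residues, residue sets, or wildcards.

    ``pattern`` is a tuple whose elements are frozensets of allowed residues,
    or ``None`` for a wildcard position.  Wildcards match any letter
    (including the unknown residue X); fixed residues and residue sets never
    match X.
    """

    name: str
    pattern: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if not self.pattern:
            raise InvalidInputError("motif pattern must be non-empty")
        for el in self.pattern:
            if el is not None and not el <= AA_ALPHABET:
                raise InvalidInputError(
                    f"motif {self.name!r} uses residues outside the amino-acid alphabet"
                )

    @classmethod
    def parse(cls, name: str, spec: str) -> "MotifSpec":
        """Parse a compact pattern: ``.`` wildcard, ``[FL]`` residue set.

        Example: ``.Y[FL]GNC`` is any residue, Y, F or L, G, N, C.
        """
        pattern: list[frozenset[str] | None] = []
        i = 0
        while i < len(spec):
            ch = spec[i]
            if ch == ".":
                pattern.append(None)
                i += 1
            elif ch == "[":
                j = spec.index("]", i)
                pattern.append(frozenset(spec[i + 1 : j]))
                i = j + 1
            else:
                pattern.append(frozenset(ch))
                i += 1
        return cls(name, tuple(pattern))

    def __len__(self) -> int:
        return len(self.pattern)

    def matches_at(self, seq: str, offset: int) -> bool:
        if offset + len(self) > len(seq):
            return False
        for k, el in enumerate(self.pattern):
            if el is None:
                continue
            if seq[offset + k] not in el:
                return False
        return True

    def find_all(self, seq: str) -> list[int]:
        """All (possibly overlapping) 0-based match offsets, left to right."""
        return [i for i in range(len(seq) - len(self) + 1) if self.matches_at(seq, i)]


#: Catalytic His...Asp motif of the BAHD superfamily.
MOTIF1 = MotifSpec.parse("HXXXD", "H...D")
#: Structural DFGWG motif near the C terminus.
MOTIF2 = MotifSpec.parse("DFGWG", "DFGWG")
#: AAT-specific motif of functional anthocyanin malonyltransferases.
MOTIF3 = MotifSpec.parse("XY[F/L]GNC", ".Y[FL]GNC")

DEFAULT_MOTIFS = (MOTIF1, MOTIF2, MOTIF3)
FILTER_MOTIF_NAME = MOTIF3.name


@dataclass
class CandidateRecord:
    """Motif-scan result for one protein sequence."""

    identifier: str
    sequence: str
    hits: dict[str, list[int]] = field(default_factory=dict)
    passes_filter: bool = False


def scan_motifs(
    identifier: str,
    sequence: str,
    specs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS,
    filter_motif: str = FILTER_MOTIF_NAME,
) -> CandidateRecord:
    """Scan one amino-acid sequence for every motif.

    The unknown residue X is accepted in the input but never matches a fixed
    residue or residue set.  ``passes_filter`` reflects the AAT-specific
    motif only.
    """
    seq = sequence.upper()
    bad = set(seq) - AA_ALPHABET - {"X", "*"}
    if bad:
        raise InvalidInputError(f"non-amino-acid letters in {identifier!r}: {sorted(bad)}")
    hits = {spec.name: spec.find_all(seq) for spec in specs}
    return CandidateRecord(
        identifier=identifier,
        sequence=sequence,
        hits=hits,
        passes_filter=bool(hits.get(filter_motif)),
    )


def filter_fasta(
    path: str | Path, specs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
) -> list[CandidateRecord]:
    """Scan every sequence of a protein FASTA file."""
    from Bio import SeqIO

    return [
        scan_motifs(rec.id, str(rec.seq).rstrip("*"), specs)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def records_to_table(records: list[CandidateRecord]) -> pd.DataFrame:
    """Candidate TSV shape: id, one presence column per motif, passes flag.

    Offsets are reported 1-based for human readability.
    """
    rows = []
    for rec in records:
        row = {"id": rec.identifier}
        for name, offs in rec.hits.items():
            row[name] = (offs[0] + 1) if offs else 0
        row["passes"] = int(rec.passes_filter)
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_segregation(observed, expected_ratio) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against an expected ratio.

    ``observed`` are category counts; ``expected_ratio`` category proportions
    (normalised to sum to one).  Returns (chi2, df, upper-tail p).
    """
    obs = pd.Series(observed, dtype=float).to_numpy()
    props = pd.Series(expected_ratio, dtype=float).to_numpy()
    if obs.sum() < 1:
        raise InvalidInputError("need at least one observation")
    if len(obs) != len(props):
        raise InvalidInputError("observed and expected lengths differ")
    total_p = props.sum()
    if total_p <= 0:
        raise InvalidExpectationError("expected proportions must sum to a positive value")
    props = props / total_p
    expected = obs.sum() * props
    if (expected == 0).any():
        raise InvalidExpectationError("zero expected count in a category")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def load_candidate_catalogue() -> pd.DataFrame:
    """The shipped catalogue of filtered maize acyltransferase candidates.

    Documentation fixture (gene identifiers and B73 RefGen_v3 coordinates of
    motif-filtered candidates); not recomputed by this package.
    """
    with resources.files("acylqtl.data").joinpath("candidate_aats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
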