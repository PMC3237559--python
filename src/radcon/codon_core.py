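"""Genetic code, amino-acid classification schemes, codon frequency tables,
per-sequence composition features and codon-alignment handling.

Everything downstream (the D_r/D_c estimator, the codon-model ML fitter, the
simulator) works on the 61 sense codons of the standard genetic code; stop
codons are excluded throughout.  A :class:`ClassificationScheme` partitions
the 20 amino acids into physiochemical groups: an amino-acid replacement that
crosses groups is *radical*, one that stays within a group is *conservative*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import gc_fraction
from Bio.SeqUtils.ProtParam import ProteinAnalysis

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
GAP = "-"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class UnresolvableCodonError(ValueError):
    """A codon contains a gap or non-ACGT character and cannot be translated."""


class SchemeConfigError(ValueError):
    """A classification scheme file does not define a valid partition."""


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


def _standard_code() -> tuple[dict[str, str], frozenset[str]]:
    table = unambiguous_dna_by_id[1]
    sense = {c: aa for c, aa in table.forward_table.items() if set(c) <= set(NUCLEOTIDES)}
    stops = frozenset(table.stop_codons)
    return sense, stops


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code restricted to unambiguous DNA codons."""

    table: Mapping[str, str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 61 or len(self.stops) != 3:
            raise ValueError("expected 61 sense and 3 stop codons")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.table))

    def translate(self, codon: str) -> str:
        """Translate one codon; returns the amino-acid letter or ``'*'`` for stops."""
        if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
            raise UnresolvableCodonError(f"unresolvable codon {codon!r}")
        if codon in self.stops:
            return STOP
        return self.table[codon]


STANDARD_CODE = GeneticCode(*_standard_code())
SENSE_CODONS: tuple[str, ...] = STANDARD_CODE.sense_codons
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA: tuple[str, ...] = tuple(STANDARD_CODE.table[c] for c in SENSE_CODONS)


def translate(codon: str) -> str:
    """Module-level shortcut for :meth:`GeneticCode.translate` on the standard code."""
    return STANDARD_CODE.translate(codon)


def is_transition(n1: str, n2: str) -> bool:
    """True when the nucleotide change n1->n2 is a transition (purine<->purine etc.)."""
    return n1 != n2 and (
        (n1 in _PURINES and n2 in _PURINES) or (n1 in _PYRIMIDINES and n2 in _PYRIMIDINES)
    )


# ---------------------------------------------------------------------------
# Classification schemes


@dataclass(frozen=True)
class ClassificationScheme:
    name: str
    groups: tuple[frozenset[str], ...]
    _group_of: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            for aa in group:
                if aa not in AMINO_ACIDS:
                    raise SchemeConfigError(f"scheme {self.name!r}: unknown letter {aa!r}")
                if aa in seen:
                    raise SchemeConfigError(f"scheme {self.name!r}: duplicated letter {aa!r}")
                seen[aa] = gi
        missing = sorted(set(AMINO_ACIDS) - set(seen))
        if missing:
            raise SchemeConfigError(
                f"scheme {self.name!r}: missing amino acid(s) {', '.join(missing)}"
            )
        if len(self.groups) < 2:
            raise SchemeConfigError(f"scheme {self.name!r}: needs at least 2 groups")
        object.__setattr__(self, "_group_of", seen)

    def group_of(self, aa: str) -> int:
        try:
            return self._group_of[aa]
        except KeyError:
            raise SchemeConfigError(f"letter {aa!r} absent from scheme {self.name!r}")

    def is_radical(self, aa1: str, aa2: str) -> bool:
        return self.group_of(aa1) != self.group_of(aa2)


def classify_change(aa1: str, aa2: str, scheme: ClassificationScheme) -> str:
    """Classify an amino-acid change as ``identical``/``conservative``/``radical``."""
    g1, g2 = scheme.group_of(aa1), scheme.group_of(aa2)
    if aa1 == aa2:
        return "identical"
    return "conservative" if g1 == g2 else "radical"


def load_scheme(path: str | Path, name: str | None = None) -> ClassificationScheme:
    """Load a classification scheme from a ``GROUPNAME: LETTERS`` text file."""
    path = Path(path)
    groups: list[frozenset[str]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise SchemeConfigError(f"{path}: malformed line {line!r}")
        _, letters = line.split(":", 1)
        groups.append(frozenset(letters.strip().upper()))
    return ClassificationScheme(name or path.stem, tuple(groups))


BUILTIN_SCHEMES = ("charge", "polarity", "MY")

_SCHEME_DIR = Path(__file__).parent / "schemes"


def builtin_scheme(name: str) -> ClassificationScheme:
    """Return a bundled scheme by name (``charge``, ``polarity`` or ``MY``).

    The HAN grouping of Hanada et al. is only defined in supplementary material
    that is not bundled; requesting it raises with instructions to supply a
    scheme file instead.
    """
    if name.upper() == "HAN":
        raise SchemeConfigError(
            "the HAN classification is not bundled (its grouping is defined only in "
            "supplementary material); transcribe it to a scheme file and use load_scheme()"
        )
    for cand in BUILTIN_SCHEMES:
        if cand.lower() == name.lower():
            return load_scheme(_SCHEME_DIR / f"{cand}.txt", name=cand)
    raise SchemeConfigError(f"unknown scheme {name!r}; built-ins: {BUILTIN_SCHEMES}")


# ---------------------------------------------------------------------------
# Codon frequency tables


@dataclass(frozen=True)
class CodonFrequencyTable:
    """Relative frequencies over the 61 sense codons (stops excluded)."""

    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = set(self.freqs) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in table: {sorted(bad)}")
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError("negative codon frequency")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"codon frequencies sum to {arr.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs.get(c, 0.0) for c in SENSE_CODONS])

    def gc_content(self) -> float:
        """Expected fraction of G+C nucleotides of a codon drawn from this table."""
        gc = np.array([sum(n in "GC" for n in c) / 3 for c in SENSE_CODONS])
        return float(self.as_array() @ gc)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CodonFrequencyTable":
        return cls(dict(zip(SENSE_CODONS, map(float, arr))))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in SENSE_CODONS:
                fh.write(f"{c}\t{self.freqs.get(c, 0.0):.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonFrequencyTable":
        freqs = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            codon, val = line.split("\t")
            freqs[codon.strip().upper()] = float(val)
        return cls(freqs)


def codon_table_from_counts(counts: Mapping[str, float]) -> CodonFrequencyTable:
    """Convert raw codon usage counts to relative frequencies over sense codons.

    Stop-codon counts are permitted in the input but ignored.
    """
    sense = {c: float(counts.get(c, 0.0)) for c in SENSE_CODONS}
    total = sum(sense.values())
    if total <= 0:
        raise ValueError("all-zero sense codon counts")
    return CodonFrequencyTable({c: v / total for c, v in sense.items()})


# ---------------------------------------------------------------------------
# Sequence composition features


@dataclass(frozen=True)
class SequenceFeatures:
    gc: float
    gravy: float
    aromaticity: float


def sequence_features(cds: str) -> SequenceFeatures:
    """%GC, mean Kyte–Doolittle hydropathy (GRAVY) and aromaticity of a CDS.

    A trailing stop codon is allowed and excluded from the protein-level
    features; internal stops are rejected.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STANDARD_CODE.stops:
        codons = codons[:-1]
    protein = "".join(translate(c) for c in codons)
    if STOP in protein:
        raise ValueError("internal stop codon in CDS")
    pa = ProteinAnalysis(protein)
    return SequenceFeatures(
        gc=gc_fraction(cds),
        gravy=pa.gravy(),
        aromaticity=pa.aromaticity(),
    )


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame aligned pair of coding sequences (column 1 = codon position 1)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise FrameError("alignment length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self) -> Iterator[tuple[str, str]]:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        for i in range(0, len(a), 3):
            yield a[i : i + 3], b[i : i + 3]

    def countable_columns(self) -> Iterator[tuple[str, str]]:
        """Codon columns where both codons are unambiguous sense codons.

        Columns with a gap or non-ACGT character in either sequence, and
        columns containing a stop codon, are excluded (pairwise deletion).
        """
        ok = set(NUCLEOTIDES)
        for ca, cb in self.codon_columns():
            if set(ca) <= ok and set(cb) <= ok:
                if ca not in STANDARD_CODE.stops and cb not in STANDARD_CODE.stops:
                    yield ca, cb

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(self.id_b, self.id_a, self.seq_b, self.seq_a)


def backtranslate(
    protein_alignment: tuple[str, str],
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Back-translate an aligned amino-acid pair onto its source CDSs.

    Each amino-acid column maps to the source codon; protein gaps become
    whole-codon ``---`` triplets.  The ungapped translation of each CDS must
    equal the ungapped protein row (a trailing stop codon on the CDS is
    tolerated and dropped).
    """

    def one_row(prot_row: str, cds: str, label: str) -> str:
        cds = cds.upper()
        if len(cds) % 3:
            raise FrameError(f"{label}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STANDARD_CODE.stops:
            codons = codons[:-1]
        residues = prot_row.replace(GAP, "")
        if len(residues) != len(codons):
            raise ValueError(
                f"{label}: protein row has {len(residues)} residues but CDS has "
                f"{len(codons)} codons"
            )
        out, k = [], 0
        for pos, aa in enumerate(prot_row):
            if aa == GAP:
                out.append(GAP * 3)
                continue
            codon = codons[k]
            if translate(codon) != aa.upper():
                raise ValueError(
                    f"{label}: translation mismatch at protein position {pos + 1}: "
                    f"codon {codon} -> {translate(codon)}, alignment says {aa}"
                )
            out.append(codon)
            k += 1
        return "".join(out)

    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    return CodonAlignment(id_a, id_b, one_row(row_a, cds_a, id_a), one_row(row_b, cds_b, id_b))


def align_proteins(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps) for building fixtures."""
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


def align_cds_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Amino-acid-level alignment of two CDSs, back-translated to codons."""

    def protein(cds: str) -> str:
        cds = cds.upper()
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STANDARD_CODE.stops:
            codons = codons[:-1]
        return "".join(translate(c) for c in codons)

    rows = align_proteins(protein(cds_a), protein(cds_b))
    return backtranslate(rows, cds_a, cds_b, id_a=id_a, id_b=id_b)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta_pair(path: str | Path) -> CodonAlignment:
    """Read a 2-record aligned FASTA file as a codon alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    a, b = records
    return CodonAlignment(a.id, b.id, str(a.seq).upper(), str(b.seq).upper())


def write_fasta_pair(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in ((aln.id_a, aln.seq_a), (aln.id_b, aln.seq_b)):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta_records(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA as an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
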