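"""Per-gene feature records and exon/intron structure analysis.

This module handles the "gene card" side of a family survey: tabulated
features of cloned genes (genomic length, CDS length, intron count, protein
size, molecular mass, isoelectric point, predicted localization) and the
exon/intron architecture of each locus.  It provides the arithmetic that
ties those columns together (CDS length -> protein length, sequence ->
average molecular mass, sequence -> pI by charge bisection), a two-class
intron-count typing used for kinase families, and an exon-structure
comparator that aligns the internal exons of a gene model against a
canonical internal-exon length list and detects exon fusions (one observed
exon whose length equals the sum of contiguous canonical exons).

Only internal exons are compared: first and last exons absorb UTR and
terminal variation, so family-level conservation statements are made about
the second-to-penultimate exons.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "InvalidCDSError",
    "UnknownResidueError",
    "StructureComparisonError",
    "CANONICAL_INTERNAL_EXONS",
    "GeneRecord",
    "ExonModel",
    "StructureEvent",
    "translate_length",
    "protein_mass",
    "net_charge",
    "isoelectric_point",
    "classify_intron_type",
    "compare_exon_structure",
    "read_gene_table",
    "read_exon_models_tsv",
    "read_exon_models_gff3",
]


class InvalidCDSError(ValueError):
    """CDS length is not a positive multiple of 3 (incl. stop codon)."""


class UnknownResidueError(ValueError):
    """Amino-acid sequence contains a symbol outside the standard 20."""


class StructureComparisonError(ValueError):
    """Gene model has no internal exons to compare."""


#: Canonical internal (second-to-eighth) exon lengths, in bp, conserved
#: across the family in eudicots and monocots alike.
CANONICAL_INTERNAL_EXONS: tuple[int, ...] = (75, 102, 54, 93, 93, 105, 99)

# Average (not monoisotopic) residue masses in Da, standard ExPASy values;
# conventional for kDa-scale reporting of protein molecular weight.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# pK sets for the Henderson-Hasselbalch charge model.  Keys: N/C termini
# plus the seven ionizable side chains.
PK_SETS: dict[str, dict[str, float]] = {
    # EMBOSS iep defaults
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    # Bjellqvist et al. values as popularized by ExPASy Compute pI/Mw
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class GeneRecord:
    """One row of a cloned-gene feature table."""

    gene_id: str
    accession: str
    gene_len_bp: int
    cds_len_bp: int
    intron_count: int
    protein_len_aa: int
    mass_kda: float
    isoelectric_point: float
    localization: str

    def validate(self) -> None:
        if self.cds_len_bp % 3 != 0:
            raise InvalidCDSError(
                f"{self.gene_id}: CDS length {self.cds_len_bp} not a multiple of 3"
            )
        if self.protein_len_aa != translate_length(self.cds_len_bp):
            raise ValueError(
                f"{self.gene_id}: protein length {self.protein_len_aa} != "
                f"CDS/3 - 1 = {translate_length(self.cds_len_bp)}"
            )
        if self.gene_len_bp < self.cds_len_bp:
            raise ValueError(f"{self.gene_id}: gene shorter than its CDS")
        per_residue = 1000.0 * self.mass_kda / self.protein_len_aa
        if not (95.0 <= per_residue <= 125.0):
            raise ValueError(
                f"{self.gene_id}: implausible mass/residue {per_residue:.1f} Da"
            )


@dataclass(frozen=True)
class ExonModel:
    """Ordered exon lengths and intron phases of one gene model."""

    gene_id: str
    exon_lengths_bp: tuple[int, ...]
    intron_phases: tuple[int, ...] = ()

    def validate(self) -> None:
        if any(l <= 0 for l in self.exon_lengths_bp):
            raise ValueError(f"{self.gene_id}: nonpositive exon length")
        if self.intron_phases and len(self.exon_lengths_bp) != len(self.intron_phases) + 1:
            raise ValueError(
                f"{self.gene_id}: exon count must equal intron count + 1"
            )
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError(f"{self.gene_id}: intron phases must be 0/1/2")

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths_bp)

    @property
    def internal_exons(self) -> tuple[int, ...]:
        return self.exon_lengths_bp[1:-1]


@dataclass(frozen=True)
class StructureEvent:
    """Outcome of aligning one observed internal exon to the canonical list.

    ``kind`` is MATCH, FUSION or MISMATCH; indices are 1-based.  For a
    FUSION, ``canon_start..canon_end`` is the contiguous canonical run whose
    summed length equals the observed exon.
    """

    kind: str
    obs_index: int | None
    canon_start: int | None
    canon_end: int | None


def translate_length(cds_len_bp: int) -> int:
    """Protein length implied by a stop-codon-inclusive CDS length."""
    if cds_len_bp < 6 or cds_len_bp % 3 != 0:
        raise InvalidCDSError(
            f"CDS length must be >= 6 and a multiple of 3, got {cds_len_bp}"
        )
    return cds_len_bp // 3 - 1


def _residue_counts(sequence: str) -> Counter:
    seq = sequence.strip().upper()
    if not seq:
        raise UnknownResidueError("empty amino-acid sequence")
    counts = Counter(seq)
    unknown = set(counts) - set(AVERAGE_RESIDUE_MASS)
    if unknown:
        raise UnknownResidueError(f"unknown residue symbol(s): {sorted(unknown)}")
    return counts


def protein_mass(sequence: str) -> float:
    """Average molecular mass of a peptide, in kDa (residue masses + water)."""
    counts = _residue_counts(sequence)
    dalton = sum(AVERAGE_RESIDUE_MASS[aa] * n for aa, n in counts.items())
    return (dalton + WATER_MASS) / 1000.0


def net_charge(sequence: str | Counter, ph: float, pk_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Positive contributions from the free N-terminus and K/R/H side chains,
    negative from the free C-terminus and D/E/C/Y side chains.
    """
    counts = sequence if isinstance(sequence, Counter) else _residue_counts(sequence)
    pk = PK_SETS[pk_set]
    pos = 1.0 / (1.0 + 10.0 ** (ph - pk["Nterm"]))
    for aa in _BASIC:
        pos += counts.get(aa, 0) / (1.0 + 10.0 ** (ph - pk[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pk["Cterm"] - ph))
    for aa in _ACIDIC:
        neg += counts.get(aa, 0) / (1.0 + 10.0 ** (pk[aa] - ph))
    return pos - neg


def isoelectric_point(
    sequence: str, pk_set: str = "emboss", tol: float = 1e-4
) -> float:
    """pH at which the peptide's net charge is zero, found by bisection.

    The charge function is strictly decreasing in pH, so bisection on
    [0, 14] converges unconditionally; iteration stops when |charge| < tol.
    """
    counts = _residue_counts(sequence)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(counts, mid, pk_set=pk_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def classify_intron_type(intron_count: int) -> str:
    """Two-class intron-count typing: 7-9 introns -> I, 5-6 -> II."""
    if intron_count < 0:
        raise ValueError(f"negative intron count {intron_count}")
    if 7 <= intron_count <= 9:
        return "I"
    if 5 <= intron_count <= 6:
        return "II"
    return "UNCLASSIFIED"


def compare_exon_structure(
    model: ExonModel,
    canonical_internal: Sequence[int] = CANONICAL_INTERNAL_EXONS,
) -> list[StructureEvent]:
    """Align a model's internal exons against the canonical length list.

    Walks both lists left to right.  Equal lengths yield MATCH; an observed
    exon equal to the sum of >=2 contiguous canonical exons starting at the
    current canonical pointer yields FUSION (shortest such merge, hence
    leftmost); anything else is a MISMATCH and both pointers advance.
    Leftover exons on either side are reported as MISMATCH with the missing
    side's indices set to None.
    """
    model.validate()
    if not canonical_internal:
        raise ValueError("canonical_internal must be non-empty")
    if len(model.exon_lengths_bp) < 3:
        raise StructureComparisonError(
            f"{model.gene_id}: need >= 3 exons to compare internal structure"
        )
    observed = model.internal_exons
    canon = tuple(canonical_internal)
    events: list[StructureEvent] = []
    i = j = 0
    while i < len(observed) and j < len(canon):
        if observed[i] == canon[j]:
            events.append(StructureEvent("MATCH", i + 1, j + 1, j + 1))
            i += 1
            j += 1
            continue
        total = canon[j]
        fusion_end = None
        for end in range(j + 1, len(canon)):
            total += canon[end]
            if total == observed[i]:
                fusion_end = end
                break
            if total > observed[i]:
                break
        if fusion_end is not None:
            events.append(StructureEvent("FUSION", i + 1, j + 1, fusion_end + 1))
            i += 1
            j = fusion_end + 1
        else:
            events.append(StructureEvent("MISMATCH", i + 1, j + 1, j + 1))
            i += 1
            j += 1
    for rest in range(i, len(observed)):
        events.append(StructureEvent("MISMATCH", rest + 1, None, None))
    for rest in range(j, len(canon)):
        events.append(StructureEvent("MISMATCH", None, rest + 1, rest + 1))
    return events


# ---------------------------------------------------------------------------
# readers

_TABLE_COLUMNS = {
    "Gene name": "gene_id",
    "Acc ID": "accession",
    "DNA(bp)": "gene_len_bp",
    "CDS(bp)": "cds_len_bp",
    "Intron": "intron_count",
    "Size(aa)": "protein_len_aa",
    "Mass(Kda)": "mass_kda",
    "IP": "isoelectric_point",
    "Subcellular localization": "localization",
}


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV feature table with the conventional column headers."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        for row in reader:
            rec = GeneRecord(
                gene_id=row["Gene name"],
                accession=row["Acc ID"],
                gene_len_bp=int(row["DNA(bp)"]),
                cds_len_bp=int(row["CDS(bp)"]),
                intron_count=int(row["Intron"]),
                protein_len_aa=int(row["Size(aa)"]),
                mass_kda=float(row["Mass(Kda)"]),
                isoelectric_point=float(row["IP"]),
                localization=row["Subcellular localization"],
            )
            records.append(rec)
    return records


def read_exon_models_tsv(path: str | Path) -> list[ExonModel]:
    """Read exon models from TSV: gene_id, comma-joined lengths, phases."""
    models = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            gene_id, lengths = row[0], row[1]
            phases = row[2] if len(row) > 2 and row[2] else ""
            model = ExonModel(
                gene_id=gene_id,
                exon_lengths_bp=tuple(int(x) for x in lengths.split(",")),
                intron_phases=tuple(int(x) for x in phases.split(",")) if phases else (),
            )
            model.validate()
            models.append(model)
    return models


def read_exon_models_gff3(path: str | Path) -> list[ExonModel]:
    """Read exon models from GFF3 (1-based inclusive; exons grouped by Parent).

    Intron phases are derived from cumulative exon length mod 3, taking the
    transcript's first exon to start in frame.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="merge",
    )
    by_parent: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        for parent in exon.attributes.get("Parent", ["?"]):
            by_parent.setdefault(parent, []).append(exon)
    models = []
    for parent, exons in sorted(by_parent.items()):
        exons.sort(key=lambda e: e.start)
        if exons and exons[0].strand == "-":
            exons.sort(key=lambda e: e.start, reverse=True)
        lengths = tuple(e.end - e.start + 1 for e in exons)
        phases = []
        cum = 0
        for l in lengths[:-1]:
            cum += l
            phases.append(cum % 3)
        model = ExonModel(parent, lengths, tuple(phases))
        model.validate()
        models.append(model)
    return models
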