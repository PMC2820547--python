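"""Per-locus alignment handling for haploid multilocus sequence data.

The central objects are :class:`LocusAlignment` (one aligned locus: ordered
strain labels times equal-length DNA rows) and :class:`MultiLocusDataset`
(several loci over the same strains plus per-strain metadata).  Gaps (``-``)
and ``N`` are treated as missing characters for site classification and
distance computation; allele identity, by contrast, is decided on the literal
uppercased string, so a ``-`` vs ``N`` mismatch yields different alleles
(strictness is conservative for clone correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LocusAlignment",
    "MultiLocusDataset",
    "SiteClassification",
    "AlignmentError",
    "read_alignment",
    "read_metadata",
    "classify_sites",
    "concatenate",
    "allele_index",
    "clone_correct",
    "write_fasta",
    "write_nexus",
]

# Residue codes: A,C,G,T -> 0..3; '-' and 'N' -> 4 (missing).
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}
# IUPAC ambiguity codes coerced to N (with a warning); '?' treated likewise.
_AMBIGUOUS = set("RYSWKMBDHVU?")

MISSING = 4


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments or datasets."""


def _sanitize_row(label: str, seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT-N")
    coerce = bad & _AMBIGUOUS
    if coerce:
        warnings.warn(
            f"sequence {label!r}: ambiguity codes {sorted(coerce)} coerced to N"
        )
        for ch in coerce:
            s = s.replace(ch, "N")
        bad -= coerce
    if bad:
        raise AlignmentError(
            f"sequence {label!r} contains characters outside ACGT-N: {sorted(bad)}"
        )
    return s


@dataclass
class LocusAlignment:
    """One aligned locus: ordered taxa and equal-length DNA rows."""

    locus_name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("number of labels and rows differ")
        if not self.rows:
            raise AlignmentError("empty alignment")
        self.rows = [
            _sanitize_row(t, r) for t, r in zip(self.taxa, self.rows)
        ]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon label(s): {dup}")
        self._codes = None

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """(n_taxa, length) uint8 matrix; A,C,G,T -> 0..3, missing -> 4."""
        if self._codes is None:
            lut = np.full(256, 255, dtype=np.uint8)
            for ch, v in _CODE.items():
                lut[ord(ch)] = v
            mat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_taxa, self.length)
            self._codes = lut[mat]
        return self._codes

    def subset(self, taxa: list[str]) -> "LocusAlignment":
        """Row subset in the given taxon order (labels must exist, exact match)."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        return LocusAlignment(
            self.locus_name, list(taxa), [self.rows[idx[t]] for t in taxa]
        )


@dataclass
class SiteClassification:
    """Per-column site classes and their counts.

    Classes: ``constant`` (at most one distinct non-missing state),
    ``informative`` (>=2 states each present in >=2 strains), ``singleton``
    (variable but not informative), ``all_missing``.
    """

    classes: list[str]
    n_constant: int
    n_variable: int
    n_singleton: int
    n_parsimony_informative: int
    n_all_missing: int
    length: int

    def informative_positions(self) -> np.ndarray:
        """0-based column indices of parsimony-informative sites."""
        return np.flatnonzero(np.asarray(self.classes) == "informative")

    def variable_positions(self) -> np.ndarray:
        cls = np.asarray(self.classes)
        return np.flatnonzero((cls == "informative") | (cls == "singleton"))


@dataclass
class MultiLocusDataset:
    """Several loci over one strain panel, with optional per-strain metadata.

    ``partition_map`` holds 1-based inclusive column ranges of each locus in
    the concatenation (external convention; all internal indexing is 0-based
    half-open).
    """

    taxa: list[str]
    loci: list[LocusAlignment]
    metadata: dict[str, dict] = field(default_factory=dict)
    partition_map: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.loci:
            raise AlignmentError("empty locus list")
        for loc in self.loci:
            if set(loc.taxa) != set(self.taxa):
                raise AlignmentError(
                    f"locus {loc.locus_name!r} taxa differ from dataset taxa"
                )
            if loc.taxa != self.taxa:
                raise AlignmentError(
                    f"locus {loc.locus_name!r} rows not in dataset taxon order"
                )
        if not self.partition_map:
            start = 1
            pm = []
            for loc in self.loci:
                pm.append((loc.locus_name, start, start + loc.length - 1))
                start += loc.length
            self.partition_map = pm

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def locus(self, name: str) -> LocusAlignment:
        for loc in self.loci:
            if loc.locus_name == name:
                return loc
        raise KeyError(name)

    def concatenated(self, name: str = "concat") -> LocusAlignment:
        rows = ["".join(loc.rows[i] for loc in self.loci) for i in range(self.n_taxa)]
        return LocusAlignment(name, list(self.taxa), rows)

    def subset(self, taxa: list[str]) -> "MultiLocusDataset":
        return MultiLocusDataset(
            list(taxa),
            [loc.subset(taxa) for loc in self.loci],
            {t: dict(self.metadata.get(t, {})) for t in taxa},
            list(self.partition_map),
        )


def read_alignment(path, fmt: str = "fasta", locus_name: str | None = None) -> LocusAlignment:
    """Read one locus alignment from FASTA or NEXUS.

    Taxon order follows file order.  Raises :class:`AlignmentError` on ragged
    rows, duplicate labels, or an empty file; IUPAC ambiguity codes other
    than N are coerced to N with a warning.
    """
    from Bio import AlignIO, SeqIO

    name = locus_name or str(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"empty or unparseable FASTA file: {path}")
        return LocusAlignment(
            name, [r.id for r in records], [str(r.seq) for r in records]
        )
    if fmt == "nexus":
        try:
            msa = AlignIO.read(str(path), "nexus")
        except Exception as exc:  # biopython raises assorted types here
            raise AlignmentError(f"cannot parse NEXUS file {path}: {exc}") from exc
        return LocusAlignment(name, [r.id for r in msa], [str(r.seq) for r in msa])
    raise ValueError(f"unknown alignment format: {fmt!r}")


def read_metadata(path) -> dict[str, dict]:
    """Read the strain metadata TSV (header: strain, species, geo, mat)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"strain"}
    if not required <= set(df.columns):
        raise AlignmentError(f"metadata must have columns incl. 'strain'; got {list(df.columns)}")
    meta = {}
    for _, row in df.iterrows():
        meta[row["strain"]] = {
            "species_label": row.get("species", ""),
            "geo_group": row.get("geo", ""),
            "mating_type": row.get("mat", ""),
        }
    return meta


def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Classify every column among non-missing residues.

    A column is *constant* when it shows at most one distinct state,
    *parsimony-informative* when >=2 states are each carried by >=2 strains,
    *singleton* when variable but not informative, and *all_missing* when no
    residue is observed.
    """
    codes = aln.codes()
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # (4, L)
    non_missing = counts.sum(axis=0)
    distinct = (counts > 0).sum(axis=0)
    states_ge2 = (counts >= 2).sum(axis=0)

    all_missing = non_missing == 0
    variable = distinct >= 2
    informative = (distinct >= 2) & (states_ge2 >= 2)
    singleton = variable & ~informative
    constant = ~all_missing & ~variable

    classes = np.full(aln.length, "constant", dtype=object)
    classes[all_missing] = "all_missing"
    classes[singleton] = "singleton"
    classes[informative] = "informative"
    return SiteClassification(
        classes=list(classes),
        n_constant=int(constant.sum()),
        n_variable=int(variable.sum()),
        n_singleton=int(singleton.sum()),
        n_parsimony_informative=int(informative.sum()),
        n_all_missing=int(all_missing.sum()),
        length=aln.length,
    )


def concatenate(
    loci: list[LocusAlignment],
    taxa_order: list[str] | None = None,
    metadata: dict[str, dict] | None = None,
) -> MultiLocusDataset:
    """Assemble loci sharing one taxon set into a :class:`MultiLocusDataset`.

    Loci may list their taxa in different orders; set equality is required.
    The concatenation follows ``taxa_order`` (default: order of the first
    locus); the partition map is recorded 1-based inclusive.
    """
    if not loci:
        raise AlignmentError("empty locus list")
    base = set(loci[0].taxa)
    for loc in loci[1:]:
        if set(loc.taxa) != base:
            only_a = base - set(loc.taxa)
            only_b = set(loc.taxa) - base
            raise AlignmentError(
                f"loci do not share a taxon set (e.g. {sorted(only_a) + sorted(only_b)})"
            )
    order = list(taxa_order) if taxa_order is not None else list(loci[0].taxa)
    if set(order) != base:
        raise AlignmentError("taxa_order must be a permutation of the shared taxon set")
    return MultiLocusDataset(
        order, [loc.subset(order) for loc in loci], metadata or {}
    )


def allele_index(ds: MultiLocusDataset) -> pd.DataFrame:
    """Per-locus allele ids (strains x loci).

    Strains whose locus sequences are identical (literal uppercased string,
    so '-' vs 'N' differ) share an id; ids are small integers in
    first-occurrence order.
    """
    data = {}
    for loc in ds.loci:
        seen: dict[str, int] = {}
        ids = []
        for row in loc.rows:
            if row not in seen:
                seen[row] = len(seen)
            ids.append(seen[row])
        data[loc.locus_name] = ids
    return pd.DataFrame(data, index=list(ds.taxa))


def clone_correct(ds: MultiLocusDataset) -> tuple[MultiLocusDataset, dict[str, list[str]]]:
    """Collapse strains with identical multilocus allele vectors.

    The first occurrence of each multilocus haplotype is retained (with its
    metadata); the mapping retained -> removed strains is returned alongside.
    Idempotent.
    """
    alleles = allele_index(ds)
    keep: list[str] = []
    mapping: dict[str, list[str]] = {}
    seen: dict[tuple, str] = {}
    for strain in ds.taxa:
        key = tuple(alleles.loc[strain])
        if key in seen:
            mapping[seen[key]].append(strain)
        else:
            seen[key] = strain
            keep.append(strain)
            mapping[strain] = []
    return ds.subset(keep), mapping


def write_fasta(aln: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def write_nexus(ds: MultiLocusDataset, path) -> None:
    """Write the concatenation as a sequential NEXUS DATA block with a
    charpartition recording the per-locus column ranges."""
    cat = ds.concatenated()
    width = max(len(t) for t in cat.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={cat.n_taxa} NCHAR={cat.length};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=N GAP=-;\n    MATRIX\n")
        for t, r in zip(cat.taxa, cat.rows):
            fh.write(f"    {t:<{width}}{r}\n")
        fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
        parts = ", ".join(
            f"{name}: {a}-{b}" for name, a, b in ds.partition_map
        )
        fh.write(f"    CHARPARTITION loci = {parts};\nEND;\n")
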