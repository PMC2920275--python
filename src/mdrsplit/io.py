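"""Tab-delimited dataset reading and writing.

The on-disk format mirrors the de-facto MDR text layout: a header row
of locus names followed by a literal ``Class`` column, then one row
per individual with genotypes in {0, 1, 2} and Class in {0, 1}
(1 = case).  Parsing is strict — any malformed token fails with the
offending line number; there is no imputation.
"""

from __future__ import annotations

from pathlib import Path

from .dataset import GenotypeDataset


class DatasetParseError(ValueError):
    """Raised with the 1-based line number of the first malformed record."""


def read_dataset(path) -> GenotypeDataset:
    """Read a strict tab-delimited case-control genotype file."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise DatasetParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[-1] != "Class":
        raise DatasetParseError(f"{path}: line 1: last header column must be 'Class'")
    locus_names = tuple(header[:-1])
    if len(set(locus_names)) != len(locus_names):
        raise DatasetParseError(f"{path}: line 1: duplicated locus name")
    n_cols = len(header)
    genotypes: list[list[int]] = []
    phenotype: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise DatasetParseError(
                f"{path}: line {lineno}: expected {n_cols} columns, found {len(fields)}"
            )
        row = []
        for name, tok in zip(locus_names, fields):
            if tok not in ("0", "1", "2"):
                raise DatasetParseError(
                    f"{path}: line {lineno}: bad genotype token {tok!r} in column {name}"
                )
            row.append(int(tok))
        if fields[-1] not in ("0", "1"):
            raise DatasetParseError(
                f"{path}: line {lineno}: bad Class token {fields[-1]!r} (must be 0 or 1)"
            )
        genotypes.append(row)
        phenotype.append(int(fields[-1]))
    if not genotypes:
        raise DatasetParseError(f"{path}: no data rows")
    return GenotypeDataset(phenotype=phenotype, genotypes=genotypes, locus_names=locus_names)


def write_dataset(data: GenotypeDataset, path) -> None:
    """Write the tab-delimited format; read→write round-trips byte-identically."""
    out = ["\t".join(data.locus_names) + "\tClass"]
    for row, label in zip(data.genotypes, data.phenotype):
        out.append("\t".join(str(int(g)) for g in row) + f"\t{int(label)}")
    Path(path).write_text("\n".join(out) + "\n")
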