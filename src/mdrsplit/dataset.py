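"""Case-control genotype container.

Genotypes are coded as minor-allele counts {0, 1, 2}; the phenotype is a
binary case/control label (1 = case).  Loci are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidGenotypeError(ValueError):
    """A genotype code outside {0, 1, 2} was encountered."""


@dataclass(frozen=True)
class GenotypeDataset:
    """An n-individual by K-locus case-control genotype table.

    Parameters
    ----------
    phenotype : array of shape (n,)
        Binary labels, 1 = case, 0 = control.
    genotypes : array of shape (n, K)
        Minor-allele counts in {0, 1, 2}.
    locus_names : tuple of str, optional
        Unique column identifiers; defaults to ``L1 .. LK``.
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    locus_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        pheno = np.ascontiguousarray(self.phenotype, dtype=np.int8)
        geno = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x loci)")
        if pheno.ndim != 1 or pheno.shape[0] != geno.shape[0]:
            raise ValueError("phenotype length must match number of genotype rows")
        if pheno.size and not np.isin(pheno, (0, 1)).all():
            raise ValueError("phenotype must be binary (0 = control, 1 = case)")
        if geno.size and (geno.min() < 0 or geno.max() > 2):
            raise InvalidGenotypeError("genotype codes must be in {0, 1, 2}")
        names = self.locus_names or tuple(f"L{i + 1}" for i in range(geno.shape[1]))
        if len(names) != geno.shape[1]:
            raise ValueError("locus_names length must match number of loci")
        if len(set(names)) != len(names):
            raise ValueError("locus_names must be unique")
        object.__setattr__(self, "phenotype", pheno)
        object.__setattr__(self, "genotypes", geno)
        object.__setattr__(self, "locus_names", tuple(names))

    @property
    def n(self) -> int:
        return int(self.phenotype.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def subset(self, indices: np.ndarray) -> "GenotypeDataset":
        """Row-subset preserving locus names."""
        idx = np.asarray(indices)
        return GenotypeDataset(self.phenotype[idx], self.genotypes[idx], self.locus_names)

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("operation requires at least one case and one control")
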