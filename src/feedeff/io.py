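"""Plain-text I/O: pedigree CSV, genotype tables, phenotype CSV, component YAML."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .components import VarianceComponents
from .genomic import GenotypeMatrix
from .pedigree import Pedigree


def read_pedigree(path) -> Pedigree:
    """Pedigree CSV with columns animal,sire,dam[,birth_year,origin]; 0 = unknown."""
    return Pedigree.from_frame(pd.read_csv(path))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Whitespace genotype table: animal id then 0/1/2 allele counts per SNP."""
    df = pd.read_csv(path, sep=r"\s+", header=None)
    ids = df.iloc[:, 0].tolist()
    codes = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    return GenotypeMatrix(ids, codes)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, animal in enumerate(geno.ids):
            fh.write(str(animal) + " " + " ".join(map(str, geno.codes[i])) + "\n")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_varcomp(path) -> VarianceComponents:
    with open(path) as fh:
        return VarianceComponents.from_dict(yaml.safe_load(fh))


def write_varcomp(vc: VarianceComponents, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vc.as_dict(), fh, sort_keys=False)


def write_ebvs(ebvs, path) -> None:
    """EBV table (Series or DataFrame indexed by animal) to CSV."""
    frame = ebvs.to_frame() if isinstance(ebvs, pd.Series) else ebvs
    frame.rename_axis("animal").to_csv(path)


def read_ebvs(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="animal")
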