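"""Plain-text readers and writers: counts / sample sheet / annotation TSV,
clinical CSV, GMT gene sets, signature tables and Newick dendrograms."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .de import Signature
from .simulate import GeneSetCollection


def read_counts_tsv(path) -> pd.DataFrame:
    """Gene x sample integer count matrix; non-integer entries are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: count matrix contains non-integer entries")
    if (values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"genotype", "chromosomal_sex", "gonadal_sex", "treatment",
                "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns "
                         f"{sorted(missing)}")
    return df


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "chromosome" not in df.columns:
        raise ValueError(f"{path}: annotation needs a 'chromosome' column")
    return df["chromosome"]


def write_annotation(annotation: pd.Series, path) -> None:
    annotation.rename("chromosome").to_csv(path, sep="\t")


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    required = {"sex", "gestational_age", "birth_weight", "bpd_status",
                "o2_at_28d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns "
                         f"{sorted(missing)}")
    return df


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path)


def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line — name, description, then tab-separated genes."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 "(need name, description, >=1 gene)")
            name, description, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name "
                                 f"{name!r}")
            sets[name] = tuple(genes)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection | dict, path,
              descriptions: dict | None = None) -> None:
    if isinstance(collection, GeneSetCollection):
        sets = collection.sets
        descriptions = collection.descriptions
    else:
        sets = collection
        descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *genes]) + "\n")


def write_signature_tsv(sig: Signature, path) -> None:
    rows = [{"gene": g, "direction": d}
            for g, d in sorted(sig.directions().items())]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False)


def read_signature_tsv(path, name: str | None = None,
                       fdr_max: float = 0.05,
                       lfc_min: float = 1.0) -> Signature:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "direction"} <= set(df.columns):
        raise ValueError(f"{path}: signature TSV needs gene and direction "
                         "columns")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: unknown directions {sorted(bad)}")
    return Signature(
        name=name or Path(path).stem,
        up=frozenset(df.loc[df["direction"] == "up", "gene"]),
        down=frozenset(df.loc[df["direction"] == "down", "gene"]),
        fdr_max=fdr_max, lfc_min=lfc_min)


def signature_to_gmt_sets(sig: Signature) -> dict[str, tuple[str, ...]]:
    """Two GMT sets per signature: NAME_UP and NAME_DN."""
    out = {}
    if sig.up:
        out[f"{sig.name}_UP"] = tuple(sorted(sig.up))
    if sig.down:
        out[f"{sig.name}_DN"] = tuple(sorted(sig.down))
    return out


def write_deg_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    out.to_csv(path, sep="\t")


def write_newick(newick: str, path) -> None:
    with open(path, "w") as handle:
        handle.write(newick if newick.endswith("\n") else newick + "\n")
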