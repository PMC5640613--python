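"""Reading and writing of extended MAF tables, gene-context tables and results.

The cohort container is a :class:`pandas.DataFrame` with one row per somatic
mutation and the canonical columns

======================  =======================================================
``gene``                HUGO symbol
``patient``             sample barcode
``classification``      one of ``indel, missense, nonsense, splice, TSS,
                        nonstop, silent``
``vaf``                 variant allele frequency, in [0, 1]
``purity``              histological tumor purity, in (0, 1]
``copy_number``         local total copy number in the tumor (default 2)
``cnv_ccf``             cancer cell fraction of an overlapping CNV (NaN if
                        absent)
``impact_raw``          raw functional-impact score on a CADD-like scale
``ccf``                 derived cancer cell fraction (NaN until derived)
``damage``              derived damage probability (NaN until derived)
======================  =======================================================

Extra columns present in the input (genomic coordinates etc.) are passed
through untouched.

The gene-context table is a gene-indexed DataFrame with columns
``n_sites_nonsyn`` (nonsynonymous sites, N_a), ``n_sites_syn`` (synonymous
sites, N_s), ``length`` (coding length in bp) and ``ncmr`` (non-coding
mutation rate per bp).
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical variant classes; everything except "silent" is protein-altering
NONSILENT_CLASSES = ("indel", "missense", "nonsense", "splice", "TSS", "nonstop")
SILENT_CLASS = "silent"
ALL_CLASSES = NONSILENT_CLASSES + (SILENT_CLASS,)

#: MAF v2.4 Variant_Classification -> canonical class
CLASSIFICATION_MAP: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice",
    "Translation_Start_Site": "TSS",
    "Nonstop_Mutation": "nonstop",
    "Frame_Shift_Del": "indel",
    "Frame_Shift_Ins": "indel",
    "In_Frame_Del": "indel",
    "In_Frame_Ins": "indel",
    "Silent": "silent",
    # canonical names map to themselves so written files round-trip
    **{c: c for c in ALL_CLASSES},
}

#: standard MAF non-coding classes, dropped with a logged count
DROPPED_CLASSES = frozenset(
    {
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "lincRNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
        "Start_Codon_SNP",
        "Start_Codon_Ins",
        "Start_Codon_Del",
    }
)

#: canonical column -> default file column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "gene": "Hugo_Symbol",
    "patient": "Tumor_Sample_Barcode",
    "classification": "Variant_Classification",
    "vaf": "VAF",
    "purity": "purity",
    "copy_number": "ploidy",
    "cnv_ccf": "CNV_CCF",
    "impact_raw": "CADD",
    "ccf": "CCF",
    "damage": "damage",
}

MANDATORY = ("gene", "patient", "classification", "vaf")

COHORT_COLUMNS = (
    "gene",
    "patient",
    "classification",
    "vaf",
    "purity",
    "copy_number",
    "cnv_ccf",
    "impact_raw",
    "ccf",
    "damage",
)


class MafFormatError(ValueError):
    """Raised when an input table violates the expected format."""


def read_maf(
    path: str | PathLike,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an extended MAF table into the canonical cohort DataFrame.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP`, keyed by canonical name
        (e.g. ``{"impact_raw": "CADD_phred"}``).

    Raises
    ------
    MafFormatError
        If a mandatory column is missing, a VAF is out of range, or a
        Variant_Classification value is unknown.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", comment="#", dtype={cmap["gene"]: str})
    for key in MANDATORY:
        if cmap[key] not in raw.columns:
            raise MafFormatError(
                f"mandatory column {cmap[key]!r} (for {key!r}) missing from {path}"
            )

    df = pd.DataFrame(index=raw.index)
    passthrough = [c for c in raw.columns if c not in set(cmap.values())]
    for key, col in cmap.items():
        if col in raw.columns:
            df[key] = raw[col]

    # defaults for absent optional columns
    if "purity" not in df:
        logger.info("no purity column; defaulting purity to 1.0 (no correction)")
        df["purity"] = 1.0
    if "copy_number" not in df:
        logger.info("no ploidy column; defaulting copy number to 2 (diploid)")
        df["copy_number"] = 2.0
    for opt in ("cnv_ccf", "impact_raw", "ccf", "damage"):
        if opt not in df:
            df[opt] = np.nan

    # classification dialect
    cls = df["classification"].astype(str)
    dropped = cls.isin(DROPPED_CLASSES)
    if dropped.any():
        logger.info("dropped %d non-coding mutation rows", int(dropped.sum()))
        df = df[~dropped].copy()
        cls = cls[~dropped]
    unknown = ~cls.isin(CLASSIFICATION_MAP)
    if unknown.any():
        bad = sorted(cls[unknown].unique())
        raise MafFormatError(f"unknown Variant_Classification value(s): {bad}")
    df["classification"] = cls.map(CLASSIFICATION_MAP)

    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    bad_rows = df.index[(vaf < 0) | (vaf > 1) | vaf.isna()]
    if len(bad_rows):
        raise MafFormatError(
            f"VAF out of range [0, 1] at input row(s) {[int(i) + 2 for i in bad_rows[:10]]}"
            " (1-based line numbers incl. header)"
        )
    df["vaf"] = vaf

    for col in ("purity", "copy_number", "cnv_ccf", "impact_raw", "ccf", "damage"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["purity"] <= 0).any() or (df["purity"] > 1).any():
        raise MafFormatError("purity must lie in (0, 1]")
    if (df["copy_number"] <= 0).any():
        raise MafFormatError("copy_number must be positive")

    df = df[list(COHORT_COLUMNS)].join(raw.loc[df.index, passthrough])
    return df.reset_index(drop=True)


def write_maf(cohort: pd.DataFrame, path: str | PathLike) -> None:
    """Write a cohort DataFrame back to the extended-MAF dialect."""
    inv = {k: v for k, v in DEFAULT_COLUMN_MAP.items() if k in cohort.columns}
    out = cohort.rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def read_gene_context(path: str | PathLike) -> pd.DataFrame:
    """Read the per-gene context table (gene, N_a, N_s, length, ncmr).

    Returns a DataFrame indexed by gene symbol with columns
    ``n_sites_nonsyn``, ``n_sites_syn``, ``length``, ``ncmr``.
    """
    raw = pd.read_csv(path, sep="\t")
    required = {"gene", "N_a", "N_s", "length", "ncmr"}
    missing = required - set(raw.columns)
    if missing:
        raise MafFormatError(f"gene-context table missing column(s) {sorted(missing)}")
    if raw["gene"].duplicated().any():
        dups = sorted(raw.loc[raw["gene"].duplicated(), "gene"].unique())
        raise MafFormatError(f"duplicate gene symbol(s) in context table: {dups[:5]}")
    ctx = raw.rename(
        columns={"N_a": "n_sites_nonsyn", "N_s": "n_sites_syn"}
    ).set_index("gene")[["n_sites_nonsyn", "n_sites_syn", "length", "ncmr"]]
    if (ctx["n_sites_nonsyn"] <= 0).any() or (ctx["n_sites_syn"] <= 0).any():
        raise MafFormatError("N_a and N_s must be positive for every gene")
    if (ctx["ncmr"] < 0).any() or (ctx["length"] <= 0).any():
        raise MafFormatError("length must be positive and ncmr nonnegative")
    return ctx


def write_gene_context(ctx: pd.DataFrame, path: str | PathLike) -> None:
    out = ctx.rename(columns={"n_sites_nonsyn": "N_a", "n_sites_syn": "N_s"})
    out.reset_index().rename(columns={"index": "gene"}).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | PathLike) -> list[str]:
    """Read a plain-text gene list (one HUGO symbol per line, # comments)."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


RESULT_COLUMNS = ("gene", "posterior_hazard", "posterior_driver", "rank", "fdr", "significant")


def write_results(results: pd.DataFrame, path: str | PathLike) -> None:
    """Write ranked per-gene results as TSV, ordered by rank."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in ("m", "n") if c in results.columns]
    out = results.sort_values("rank")[cols + extra]
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ranking(path: str | PathLike, gene_col: str = "gene", rank_col: str | None = "rank") -> list[str]:
    """Read an external ranked gene list (TSV) into rank order.

    Accepts either a results TSV with a rank column or any TSV already
    sorted best-first.
    """
    df = pd.read_csv(path, sep="\t")
    if rank_col and rank_col in df.columns:
        df = df.sort_values(rank_col)
    return df[gene_col].astype(str).tolist()
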