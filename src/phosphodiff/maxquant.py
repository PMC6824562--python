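"""Readers for MaxQuant-style quantification tables.

Handles the two dialects a SILAC spike-in study produces: a
``proteinGroups``-like table (one row per protein group, per-sample
normalized H/L ratio and iBAQ columns) and a ``Phospho(STY)Sites``-like table
(one row per site, ratio columns optionally split by phosphorylation
multiplicity ``___1/___2/___3``). Column names are bound through configurable
templates because MaxQuant dialects drift across versions.

Zeros in ratio/intensity columns are converted to missing (the MaxQuant
convention for "not quantified"); artifact rows are flagged with "+" in the
contaminant / reverse / only-identified-by-site columns and removed by
:func:`filter_artifacts`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import (
    FLAG_COLUMNS,
    PHOSPHO,
    PROTEOME,
    ConfigurationError,
    DesignError,
    FeatureTable,
    StudyDesign,
)

log = logging.getLogger(__name__)

MULTIPLICITIES = ("___1", "___2", "___3")


@dataclass(frozen=True)
class ColumnTemplates:
    """Column-name templates binding samples to matrix columns."""

    ratio: str = "Ratio H/L normalized {sample}"
    ibaq: str = "iBAQ {sample}"
    id_proteome: str = "Majority protein IDs"
    gene: str = "Gene names"
    protein_phospho: str = "Protein"
    amino_acid: str = "Amino acid"
    position: str = "Position"
    localization_prob: str = "Localization prob"
    contaminant: str = "Potential contaminant"
    reverse: str = "Reverse"
    only_identified_by_site: str = "Only identified by site"


def _flag_series(frame: pd.DataFrame, column: str) -> pd.Series:
    if column in frame.columns:
        return frame[column].fillna("").astype(str).eq("+")
    return pd.Series(False, index=frame.index)


def _numeric(frame: pd.DataFrame, column: str) -> pd.Series:
    """Numeric column with MaxQuant zero-as-missing decoding."""
    values = pd.to_numeric(frame[column], errors="coerce")
    return values.mask(values == 0)


def _resolve(frame: pd.DataFrame, template: str, samples: list[str], what: str) -> dict[str, str]:
    columns = {s: template.format(sample=s) for s in samples}
    missing = [c for s, c in columns.items() if c not in frame.columns]
    if missing:
        present = any(c in frame.columns for c in columns.values())
        if present:
            raise DesignError(f"samples in design absent from file ({what}): {missing}")
        raise ConfigurationError(f"missing mandatory {what} columns, e.g. {missing[0]!r}")
    return columns


def read_quant_table(
    path,
    design: StudyDesign,
    layer: str,
    templates: ColumnTemplates | None = None,
) -> FeatureTable:
    """Read a MaxQuant-style TSV into a :class:`FeatureTable`.

    Proteome rows are keyed by the protein-group accession column; phospho
    rows by ``ACCESSION_<residue><position>``. Phosphosite multiplicity
    columns are collapsed by keeping, per site, the multiplicity with the
    fewest missing values (ties favor the lowest multiplicity).
    """
    tpl = templates or ColumnTemplates()
    frame = pd.read_csv(path, sep="\t", low_memory=False)
    if layer == PROTEOME:
        return _read_proteome(frame, design, tpl)
    if layer == PHOSPHO:
        return _read_phospho(frame, design, tpl)
    raise ConfigurationError(f"unknown layer {layer!r}")


def _read_proteome(frame: pd.DataFrame, design: StudyDesign, tpl: ColumnTemplates) -> FeatureTable:
    if tpl.id_proteome not in frame.columns:
        raise ConfigurationError(f"missing mandatory column {tpl.id_proteome!r}")
    samples = design.samples
    ratio_cols = _resolve(frame, tpl.ratio, samples, "ratio")
    ibaq_cols = _resolve(frame, tpl.ibaq, samples, "iBAQ")

    feature_id = frame[tpl.id_proteome].astype(str)
    ratios = pd.DataFrame({s: _numeric(frame, c) for s, c in ratio_cols.items()})
    ibaq = pd.DataFrame({s: _numeric(frame, c) for s, c in ibaq_cols.items()})
    flags = pd.DataFrame(
        {
            "contaminant": _flag_series(frame, tpl.contaminant),
            "reverse": _flag_series(frame, tpl.reverse),
            "only_identified_by_site": _flag_series(frame, tpl.only_identified_by_site),
        }
    )
    genes = frame[tpl.gene].astype(str) if tpl.gene in frame.columns else feature_id
    for df in (ratios, ibaq, flags):
        df.index = pd.Index(np.asarray(feature_id, dtype=object))
    genes.index = ratios.index
    return FeatureTable(
        ratios=ratios, design=design, layer=PROTEOME, ibaq=ibaq,
        flags=flags, gene_symbols=genes.rename("gene_symbols"),
    )


def _read_phospho(frame: pd.DataFrame, design: StudyDesign, tpl: ColumnTemplates) -> FeatureTable:
    for col in (tpl.protein_phospho, tpl.amino_acid, tpl.position):
        if col not in frame.columns:
            raise ConfigurationError(f"missing mandatory column {col!r}")
    samples = design.samples

    # Site ratios may be plain or split by multiplicity; collapse per site.
    plain = {s: tpl.ratio.format(sample=s) for s in samples}
    if all(c in frame.columns for c in plain.values()):
        ratios = pd.DataFrame({s: _numeric(frame, c) for s, c in plain.items()})
    else:
        candidates: list[pd.DataFrame] = []
        for mult in MULTIPLICITIES:
            cols = {s: tpl.ratio.format(sample=s) + mult for s in samples}
            if all(c in frame.columns for c in cols.values()):
                candidates.append(pd.DataFrame({s: _numeric(frame, c) for s, c in cols.items()}))
        if not candidates:
            raise ConfigurationError(
                f"missing mandatory ratio columns, e.g. {list(plain.values())[0]!r}"
            )
        # least-missing multiplicity wins, row by row
        counts = np.column_stack([c.notna().sum(axis=1).to_numpy() for c in candidates])
        best = counts.argmax(axis=1)
        stacked = np.stack([c.to_numpy() for c in candidates])  # mult x row x sample
        ratios = pd.DataFrame(
            stacked[best, np.arange(len(frame))], columns=samples, index=frame.index
        )

    residue = frame[tpl.amino_acid].astype(str)
    bad = ~residue.isin(["S", "T", "Y"])
    if bad.any():
        raise ConfigurationError(
            f"phosphosite residue must be S/T/Y, got {residue[bad].iloc[0]!r}"
        )
    acc = frame[tpl.protein_phospho].astype(str)
    pos = pd.to_numeric(frame[tpl.position], errors="coerce").astype("Int64")
    feature_id = acc + "_" + residue + pos.astype(str)

    flags = pd.DataFrame(
        {
            "contaminant": _flag_series(frame, tpl.contaminant),
            "reverse": _flag_series(frame, tpl.reverse),
            "only_identified_by_site": pd.Series(False, index=frame.index),
        }
    )
    genes = frame[tpl.gene].astype(str) if tpl.gene in frame.columns else acc
    extra = None
    if tpl.localization_prob in frame.columns:
        extra = pd.DataFrame(
            {"localization_prob": pd.to_numeric(frame[tpl.localization_prob], errors="coerce")}
        )
        extra.index = feature_id
    for df in (ratios, flags):
        df.index = pd.Index(np.asarray(feature_id, dtype=object))
    genes.index = ratios.index
    if extra is not None:
        extra.index = ratios.index
    return FeatureTable(
        ratios=ratios, design=design, layer=PHOSPHO, ibaq=None,
        flags=flags, gene_symbols=genes.rename("gene_symbols"), extra=extra,
    )


def filter_artifacts(table: FeatureTable) -> FeatureTable:
    """Discard contaminant, reverse-hit and only-identified-by-site records.

    Order is preserved; the removal count per flag is logged. Idempotent.
    """
    flags = table.flags
    for flag in FLAG_COLUMNS:
        n = int(flags[flag].sum())
        if n:
            log.info("filter_artifacts: removing %d records flagged %s", n, flag)
    keep = ~flags[list(FLAG_COLUMNS)].any(axis=1)
    return table.subset(table.feature_ids[keep])
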