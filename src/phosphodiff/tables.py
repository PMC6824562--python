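"""Core containers: the study design and the feature-by-sample quantification table.

A SILAC spike-in experiment quantifies every sample against one common heavy
reference, so each cell of the matrix is a linear H/L-style ratio. Features are
protein groups (proteome layer) or phosphosites (phosphoproteome layer,
keyed ``ACCESSION_S123``). Missing quantifications are NaN; MaxQuant encodes
them as 0, which the readers convert on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PROTEOME = "proteome"
PHOSPHO = "phosphoproteome"
LAYERS = (PROTEOME, PHOSPHO)

GROUPS = ("benign", "CS", "CR")

FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")


class DesignError(ValueError):
    """The study design is inconsistent with the data or with itself."""


class ConfigurationError(ValueError):
    """A required column, parameter or file is missing or malformed."""


@dataclass(frozen=True)
class StudyDesign:
    """Maps each sample to its cell line, replicate number and biological group.

    Groups follow the castration-response vocabulary: ``benign`` for the
    non-tumorigenic reference line, ``CS`` for the castration-sensitive line
    and ``CR`` for castration-resistant lines.
    """

    frame: pd.DataFrame  # index: sample_id; columns: cell_line, replicate, group

    def __post_init__(self) -> None:
        required = {"cell_line", "replicate", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DesignError(f"design missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()].tolist()
            raise DesignError(f"duplicate sample ids in design: {dup}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise DesignError(f"unknown groups {sorted(bad)}; expected one of {GROUPS}")
        if (self.frame["replicate"] < 1).any():
            raise DesignError("replicate numbers must be positive integers")

    # -- accessors -----------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def cell_lines(self) -> list[str]:
        seen: list[str] = []
        for line in self.frame["cell_line"]:
            if line not in seen:
                seen.append(line)
        return seen

    def samples_for_line(self, line: str) -> list[str]:
        return list(self.frame.index[self.frame["cell_line"] == line])

    def line_of(self, sample: str) -> str:
        return str(self.frame.loc[sample, "cell_line"])

    def group_of_line(self, line: str) -> str:
        groups = set(self.frame.loc[self.frame["cell_line"] == line, "group"])
        if len(groups) != 1:
            raise DesignError(f"cell line {line!r} maps to groups {sorted(groups)}")
        return groups.pop()

    def lines_in_group(self, group: str) -> list[str]:
        return [ln for ln in self.cell_lines if self.group_of_line(ln) == group]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    @property
    def cs_line(self) -> str:
        lines = self.lines_in_group("CS")
        if len(lines) != 1:
            raise DesignError(f"expected exactly one CS cell line, found {lines}")
        return lines[0]

    @property
    def cr_lines(self) -> list[str]:
        lines = self.lines_in_group("CR")
        if not lines:
            raise DesignError("no CR cell line in design")
        return lines

    @property
    def reference_line(self) -> str:
        lines = self.lines_in_group("benign")
        if len(lines) != 1:
            raise DesignError(f"expected exactly one benign reference line, found {lines}")
        return lines[0]

    # -- editing -------------------------------------------------------------

    def drop_sample(self, sample_id: str) -> "StudyDesign":
        if sample_id not in self.frame.index:
            raise DesignError(f"unknown sample {sample_id!r}")
        reduced = self.frame.drop(index=sample_id)
        line = self.frame.loc[sample_id, "cell_line"]
        if (reduced["cell_line"] == line).sum() < 2:
            raise DesignError(
                f"dropping {sample_id!r} would leave cell line {line!r} with <2 samples"
            )
        return StudyDesign(reduced)

    # -- serialization -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, group_map: dict[str, str] | None = None) -> "StudyDesign":
        """Read a design TSV (sample_id, cell_line, replicate[, group]).

        If the file has no ``group`` column, ``group_map`` (cell_line -> group)
        must supply it.
        """
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
        if "sample_id" not in frame.columns:
            raise ConfigurationError("design file must have a 'sample_id' column")
        frame = frame.set_index("sample_id")
        if "group" not in frame.columns:
            if group_map is None:
                raise ConfigurationError(
                    "design file has no 'group' column and no group map was given"
                )
            unknown = set(frame["cell_line"]) - set(group_map)
            if unknown:
                raise ConfigurationError(f"group map missing cell lines: {sorted(unknown)}")
            frame["group"] = frame["cell_line"].map(group_map)
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class FeatureTable:
    """Quantification matrix plus per-feature metadata for one omic layer.

    ``ratios`` and ``ibaq`` are feature x sample frames (NaN = missing,
    strictly positive where present). ``flags`` carries the MaxQuant artifact
    booleans; ``gene_symbols`` a semicolon-joined symbol string per feature.
    """

    ratios: pd.DataFrame
    design: StudyDesign
    layer: str
    ibaq: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    gene_symbols: pd.Series | None = None
    extra: pd.DataFrame | None = None  # e.g. localization probability

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigurationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if list(self.ratios.columns) != self.design.samples:
            raise DesignError(
                "ratio matrix samples do not match design: "
                f"{list(self.ratios.columns)} vs {self.design.samples}"
            )
        if self.ratios.index.has_duplicates:
            dup = self.ratios.index[self.ratios.index.duplicated()].tolist()
            raise ConfigurationError(f"duplicate feature ids: {dup[:5]}")
        with np.errstate(invalid="ignore"):
            if (self.ratios.to_numpy() <= 0).any():
                bad = self.ratios.index[(self.ratios <= 0).any(axis=1)][0]
                raise ConfigurationError(f"non-positive ratio for feature {bad!r}")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.ratios.index, columns=list(FLAG_COLUMNS)
            )
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series(
                self.ratios.index, index=self.ratios.index, name="gene_symbols"
            )

    # -- basics --------------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.ratios.index

    def __len__(self) -> int:
        return len(self.ratios)

    def subset(self, feature_ids) -> "FeatureTable":
        idx = self.ratios.index.intersection(pd.Index(feature_ids), sort=False)
        return replace(
            self,
            ratios=self.ratios.loc[idx],
            ibaq=None if self.ibaq is None else self.ibaq.loc[idx],
            flags=self.flags.loc[idx],
            gene_symbols=self.gene_symbols.loc[idx],
            extra=None if self.extra is None else self.extra.loc[idx],
        )

    def drop_sample(self, sample_id: str) -> "FeatureTable":
        """Remove one sample from the matrix and the design.

        Downstream "n of m replicates" rules then see the reduced replicate
        count for that cell line.
        """
        if sample_id not in self.ratios.columns:
            raise DesignError(f"unknown sample {sample_id!r}")
        design = self.design.drop_sample(sample_id)
        return replace(
            self,
            ratios=self.ratios.drop(columns=sample_id),
            ibaq=None if self.ibaq is None else self.ibaq.drop(columns=sample_id),
            design=design,
        )

    def primary_gene(self) -> pd.Series:
        """First listed gene symbol per feature (complex resources are symbol-keyed)."""
        return self.gene_symbols.fillna("").str.split(";").str[0]

    # -- internal TSV serialization -----------------------------------------

    def to_tsv(self, path) -> None:
        """Canonical internal dialect: metadata columns then ratio_/ibaq_ per sample."""
        out = pd.DataFrame(index=self.ratios.index)
        out["layer"] = self.layer
        out["gene_symbols"] = self.gene_symbols
        for flag in FLAG_COLUMNS:
            out[flag] = self.flags[flag].map({True: "+", False: ""})
        for s in self.design.samples:
            out[f"ratio_{s}"] = self.ratios[s]
        if self.ibaq is not None:
            for s in self.design.samples:
                out[f"ibaq_{s}"] = self.ibaq[s]
        out.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, design: StudyDesign) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t", index_col="feature_id")
        layers = set(frame["layer"])
        if len(layers) != 1:
            raise ConfigurationError(f"mixed layers in internal table: {sorted(layers)}")
        ratio_cols = {s: f"ratio_{s}" for s in design.samples}
        missing = [c for c in ratio_cols.values() if c not in frame.columns]
        if missing:
            raise DesignError(f"samples in design absent from file: {missing}")
        ratios = frame[list(ratio_cols.values())].copy()
        ratios.columns = design.samples
        ibaq = None
        if all(f"ibaq_{s}" in frame.columns for s in design.samples):
            ibaq = frame[[f"ibaq_{s}" for s in design.samples]].copy()
            ibaq.columns = design.samples
        flags = pd.DataFrame(
            {f: frame[f].fillna("").eq("+") for f in FLAG_COLUMNS}, index=frame.index
        )
        for df in (ratios, ibaq, flags):
            if df is not None:
                df.index.name = None
        return cls(
            ratios=ratios,
            design=design,
            layer=layers.pop(),
            ibaq=ibaq,
            flags=flags,
            gene_symbols=frame["gene_symbols"].astype(str),
        )


def parse_site_key(site_id: str) -> tuple[str, str, int]:
    """Split ``ACC_S123`` into (accession, residue, 1-based position)."""
    acc, _, tail = site_id.rpartition("_")
    if not acc or len(tail) < 2 or tail[0] not in "STY":
        raise ConfigurationError(f"malformed phosphosite key {site_id!r}")
    try:
        pos = int(tail[1:])
    except ValueError:
        raise ConfigurationError(f"malformed phosphosite key {site_id!r}") from None
    if pos < 1:
        raise ConfigurationError(f"phosphosite position must be >= 1 in {site_id!r}")
    return acc, tail[0], pos
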