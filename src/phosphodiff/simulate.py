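"""Synthetic SILAC proteome + phosphoproteome generator with planted truth.

Emulates the statistical shape of a spike-in SILAC study of four prostate
cell lines (one benign reference, one castration-sensitive, two
castration-resistant; three replicates each): linear H/L ratios that are
log-normal around 1, an S-shaped iBAQ abundance curve spanning ~6 orders of
magnitude, abundance-dependent (missing-not-at-random) dropout, and planted
structure for every downstream stage — housekeeping block, per-line and
CR-vs-CS differential blocks, presence/absence blocks, an active kinase and
an overdispersed module. The ground truth is machine-readable so recovery
can be scored.

Background features carry broad random per-line effects — distinct cell
lines genuinely differ in much of their proteome — while planted blocks
override those effects so their contrasts are exact; effective truth sets
are derived from the noiseless signal. All randomness flows from one seed
through named substreams, so adding one planted block never perturbs the
draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import PHOSPHO, PROTEOME, ConfigurationError, FeatureTable, StudyDesign

DEFAULT_LINES = {"BEN": "benign", "CSL": "CS", "CRA": "CR", "CRB": "CR"}


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults mirror a four-line, three-replicate study."""

    n_proteins: int = 3200
    n_sites: int = 3700
    lines: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINES))
    replicates: int = 3
    # abundance model: log10 iBAQ follows a logistic (S-shaped rank) curve
    dynamic_orders: float = 6.0
    ibaq_center_log10: float = 7.0
    ibaq_rep_sd_log10: float = 0.15
    # expression model (log2 ratio scale)
    baseline_sd: float = 0.5
    # broad per-(feature, cancer-line) expression effects: cell lines differ in
    # much of their proteome, which is what makes BH lenient enough to matter;
    # planted blocks override these so their effect sizes are exact
    line_effect_sd: float = 0.8
    noise_sd: float = 0.3
    # missing-not-at-random dropout: logistic in log10 abundance above the floor
    dropout_mid_orders: float = 2.7
    dropout_scale_orders: float = 0.35
    uniform_dropout: float = 0.05
    phospho_extra_orders: float = 0.2  # sites detect worse than their parents
    # planted blocks
    n_housekeeping: int = 300
    n_de_per_line: int = 50        # per cancer line, half up / half down
    n_common_de: int = 30          # shared by all cancer lines, half up / half down
    n_cr_de: int = 80              # CR-vs-CS block, half up / half down
    de_effect_log2: float = 2.0
    n_cr_only: int = 20
    n_cs_only: int = 10
    n_cr_only_sites: int = 5
    n_cs_only_sites: int = 20
    n_sites_cr_de: int = 40        # phospho CR-vs-CS block, half up / half down
    # kinase layer
    n_kinases: int = 20
    substrates_per_kinase: int = 8
    kinase_effect_log2: float = 1.25  # ~1.5x the SD of consistent-site scores
    # module layer
    n_modules: int = 10
    module_size: int = 15
    module_loading: float = 0.8
    module_noise_sd: float = 0.6
    # cross-layer coupling: site log2 = w * parent + sqrt(1-w^2) * own;
    # with the default line-effect variance this puts the per-line Pearson
    # correlation between protein and site-mean expression near 0.5
    site_parent_weight: float = 0.3
    # artifact rows prepended to the written tables
    n_contaminants: int = 60
    n_reverse: int = 30
    n_only_by_site: int = 60
    # complex resources for the network stage
    n_complexes: int = 150
    complex_size_range: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_housekeeping
            + self.n_de_per_line * 3
            + self.n_common_de
            + self.n_cr_de
            + self.n_cr_only
            + self.n_cs_only
            + self.n_modules * self.module_size
        )
        if planted > self.n_proteins:
            raise ConfigurationError(
                f"planted protein blocks ({planted}) exceed n_proteins ({self.n_proteins})"
            )
        site_planted = (
            self.n_cr_only_sites + self.n_cs_only_sites + self.n_sites_cr_de
            + self.n_kinases * self.substrates_per_kinase
        )
        if site_planted > self.n_sites:
            raise ConfigurationError(
                f"planted site blocks ({site_planted}) exceed n_sites ({self.n_sites})"
            )
        for name, sd in (("baseline_sd", self.baseline_sd), ("noise_sd", self.noise_sd),
                         ("module_noise_sd", self.module_noise_sd)):
            if sd <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    """Planted block memberships and the maps used to plant them."""

    blocks: dict[str, list[str]]
    ks_map: dict[str, list[str]]          # kinase -> substrate site ids
    active_kinase: str
    modules: dict[str, list[str]]         # module -> gene symbols
    overdispersed_module: str
    protein_gene: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "blocks": self.blocks,
                    "ks_map": self.ks_map,
                    "active_kinase": self.active_kinase,
                    "modules": self.modules,
                    "overdispersed_module": self.overdispersed_module,
                    "protein_gene": self.protein_gene,
                },
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of the draws of every other block."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def make_design(config: SyntheticConfig) -> StudyDesign:
    rows = []
    for line, group in config.lines.items():
        for rep in range(1, config.replicates + 1):
            rows.append({"sample_id": f"{line}_{rep}", "cell_line": line,
                         "replicate": rep, "group": group})
    frame = pd.DataFrame(rows).set_index("sample_id")
    return StudyDesign(frame)


def _sigmoid_rank_log10(n: int, orders: float, center: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-quantile abundances: the rank plot of log10 iBAQ is S-shaped."""
    u = (np.arange(n) + 0.5) / n
    scale = orders / (2 * np.log10(2 * n - 1))
    log10 = center + scale * np.log10(u / (1 - u))
    return rng.permutation(log10)


def _assign_blocks(config: SyntheticConfig, protein_ids: list[str]) -> dict[str, list[str]]:
    """Deterministic disjoint slices of the protein id list, shuffled once."""
    rng = _rng(config.seed, "protein-block-assignment")
    pool = list(rng.permutation(protein_ids))
    blocks: dict[str, list[str]] = {}

    def take(name: str, n: int) -> None:
        blocks[name] = sorted(pool[:n])
        del pool[:n]

    take("housekeeping", config.n_housekeeping)
    half = config.n_de_per_line // 2
    for line, group in config.lines.items():
        if group == "benign":
            continue
        take(f"{line}_up", half)
        take(f"{line}_down", config.n_de_per_line - half)
    take("common_up", config.n_common_de // 2)
    take("common_down", config.n_common_de - config.n_common_de // 2)
    take("CR_up", config.n_cr_de // 2)
    take("CR_down", config.n_cr_de - config.n_cr_de // 2)
    take("CR_only", config.n_cr_only)
    take("CS_only", config.n_cs_only)
    for m in range(config.n_modules):
        take(f"module_{m:02d}", config.module_size)
    return blocks


def generate(config: SyntheticConfig) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Build the proteome and phosphoproteome tables plus their ground truth."""
    design = make_design(config)
    samples = design.samples
    n, s = config.n_proteins, len(samples)
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    gene_symbols = {p: f"G{i:05d}" for i, p in enumerate(protein_ids, start=1)}
    blocks = _assign_blocks(config, protein_ids)
    idx_of = {p: i for i, p in enumerate(protein_ids)}
    cancer_lines = [ln for ln, g in config.lines.items() if g != "benign"]
    cs_line = design.cs_line
    cr_lines = design.cr_lines
    col_of_line = {ln: [samples.index(x) for x in design.samples_for_line(ln)] for ln in config.lines}

    # --- abundance ---------------------------------------------------------
    rng_ab = _rng(config.seed, "abundance")
    log10_base = _sigmoid_rank_log10(n, config.dynamic_orders, config.ibaq_center_log10, rng_ab)
    hk_rows = [idx_of[p] for p in blocks["housekeeping"]]
    top = config.ibaq_center_log10 + config.dynamic_orders / 2
    log10_base[hk_rows] = rng_ab.uniform(top - 0.8, top, size=len(hk_rows))

    # --- expression signal (log2 ratio scale) ------------------------------
    rng_ex = _rng(config.seed, "protein-expression")
    baseline = rng_ex.normal(0.0, config.baseline_sd, size=n)
    signal = np.tile(baseline[:, None], (1, s))
    # broad per-(feature, line) effects — cell lines differ in much of their
    # proteome — except on planted rows, whose contrasts must be exact
    planted_de = [
        idx_of[p]
        for name, members in blocks.items()
        if name not in ("housekeeping", "CR_only", "CS_only")
        for p in members
    ]
    if config.line_effect_sd > 0:
        for ln, cols in col_of_line.items():
            eff = rng_ex.normal(0.0, config.line_effect_sd, size=n)
            eff[planted_de] = 0.0
            signal[:, cols] += eff[:, None]

    e = config.de_effect_log2

    def shift(block: str, lines: list[str], delta: float) -> None:
        rows = [idx_of[p] for p in blocks[block]]
        for ln in lines:
            signal[np.ix_(rows, col_of_line[ln])] += delta

    for ln in cancer_lines:
        shift(f"{ln}_up", [ln], +e)
        shift(f"{ln}_down", [ln], -e)
    shift("common_up", cancer_lines, +e)
    shift("common_down", cancer_lines, -e)
    shift("CR_up", cr_lines, +e / 2)
    shift("CR_up", [cs_line], -e / 2)
    shift("CR_down", cr_lines, -e / 2)
    shift("CR_down", [cs_line], +e / 2)

    noise = rng_ex.normal(0.0, config.noise_sd, size=(n, s))

    # planted overdispersed module: shared latent factor replaces the noise model
    rng_mod = _rng(config.seed, "module-factor")
    module_names = [f"module_{m:02d}" for m in range(config.n_modules)]
    overdispersed = module_names[0] if module_names else ""
    if overdispersed:
        factor = rng_mod.normal(0.0, 1.0, size=s)
        rows = [idx_of[p] for p in blocks[overdispersed]]
        signs = np.where(rng_mod.random(len(rows)) < 0.5, -1.0, 1.0)
        noise[rows, :] = (
            config.module_loading * signs[:, None] * factor[None, :]
            + config.module_noise_sd * rng_mod.normal(0.0, 1.0, size=(len(rows), s))
        )

    log2_ratio = signal + noise

    # effective truth from the noiseless signal: a planted shift in one
    # comparison can imply truth in another (a CS-only downshift is a genuine
    # resistance marker), so truth sets are derived from group means of the
    # signal rather than from block membership alone
    effective = _effective_truth(signal, protein_ids, design, col_of_line, prefix="")

    # --- dropout (missing-not-at-random) ------------------------------------
    rng_drop = _rng(config.seed, "protein-dropout")
    floor = config.ibaq_center_log10 - config.dynamic_orders / 2
    depth = log10_base - floor
    p_drop = 1.0 / (1.0 + np.exp((depth - config.dropout_mid_orders) / config.dropout_scale_orders))
    missing = rng_drop.random((n, s)) < p_drop[:, None]
    missing |= rng_drop.random((n, s)) < config.uniform_dropout

    protected = set()
    for name in blocks:
        if name in ("CR_only", "CS_only"):
            continue
        protected.update(blocks[name])
    prot_rows = [idx_of[p] for p in protected]
    missing[prot_rows, :] = False

    cs_cols = col_of_line[cs_line]
    cr_cols = [c for ln in cr_lines for c in col_of_line[ln]]
    ben_cols = col_of_line[design.reference_line]
    for p in blocks["CR_only"]:
        i = idx_of[p]
        missing[i, :] = False
        missing[i, cs_cols] = True
        missing[i, ben_cols] = True
    for p in blocks["CS_only"]:
        i = idx_of[p]
        missing[i, :] = False
        missing[i, cr_cols] = True
        missing[i, ben_cols] = True

    # guard: no unplanted feature may satisfy the presence/absence rule
    planted_pa = {idx_of[p] for p in blocks["CR_only"]} | {idx_of[p] for p in blocks["CS_only"]}
    _guard_presence_absence(missing, cs_cols, cr_cols, planted_pa)

    ratios = pd.DataFrame(np.exp2(log2_ratio), index=protein_ids, columns=samples)
    ratios = ratios.mask(missing)
    rng_ib = _rng(config.seed, "ibaq-noise")
    ibaq = pd.DataFrame(
        np.power(10.0, log10_base[:, None] + rng_ib.normal(0, config.ibaq_rep_sd_log10, (n, s))),
        index=protein_ids, columns=samples,
    ).mask(missing)

    genes = pd.Series({p: gene_symbols[p] for p in protein_ids}, name="gene_symbols")
    proteome = FeatureTable(
        ratios=ratios, design=design, layer=PROTEOME, ibaq=ibaq,
        gene_symbols=genes.loc[protein_ids],
    )

    phospho, site_blocks, ks_map, active_kinase = _generate_phospho(
        config, design, protein_ids, gene_symbols, signal, log2_ratio, log10_base
    )

    truth_blocks = dict(blocks)
    truth_blocks.update(effective)
    truth_blocks.update(site_blocks)
    truth = GroundTruth(
        blocks={k: sorted(v) for k, v in truth_blocks.items()},
        ks_map={k: sorted(v) for k, v in ks_map.items()},
        active_kinase=active_kinase,
        modules={
            name: sorted(gene_symbols[p] for p in blocks[name]) for name in module_names
        },
        overdispersed_module=overdispersed,
        protein_gene=gene_symbols,
    )
    return proteome, phospho, truth


def _effective_truth(
    signal: np.ndarray,
    ids: list[str],
    design: StudyDesign,
    col_of_line: dict[str, list[int]],
    prefix: str = "",
    tol: float = 1e-9,
) -> dict[str, list[str]]:
    """Truth sets implied by the noiseless signal's group means.

    Keys: ``true_{prefix}anova``, ``true_{prefix}{line}_up/down`` (vs the
    benign reference), ``true_{prefix}CR_up/down`` (consistent in every
    CR-vs-CS comparison) and ``true_{prefix}common_up/down``.
    """
    ids_arr = np.asarray(ids)
    means = {ln: signal[:, cols].mean(axis=1) for ln, cols in col_of_line.items()}
    ref, cs, crs = design.reference_line, design.cs_line, design.cr_lines
    cancer = [ln for ln in col_of_line if ln != ref]
    out: dict[str, list[str]] = {}
    stack = np.stack(list(means.values()))
    out[f"true_{prefix}anova"] = sorted(ids_arr[stack.max(axis=0) - stack.min(axis=0) > tol])
    for ln in cancer:
        d = means[ln] - means[ref]
        out[f"true_{prefix}{ln}_up"] = sorted(ids_arr[d > tol])
        out[f"true_{prefix}{ln}_down"] = sorted(ids_arr[d < -tol])
    up = np.ones(len(ids_arr), bool)
    down = np.ones(len(ids_arr), bool)
    for ln in crs:
        d = means[ln] - means[cs]
        up &= d > tol
        down &= d < -tol
    out[f"true_{prefix}CR_up"] = sorted(ids_arr[up])
    out[f"true_{prefix}CR_down"] = sorted(ids_arr[down])
    cup = np.ones(len(ids_arr), bool)
    cdown = np.ones(len(ids_arr), bool)
    for ln in cancer:
        d = means[ln] - means[ref]
        cup &= d > tol
        cdown &= d < -tol
    out[f"true_{prefix}common_up"] = sorted(ids_arr[cup])
    out[f"true_{prefix}common_down"] = sorted(ids_arr[cdown])
    return out


def _guard_presence_absence(
    missing: np.ndarray, cs_cols: list[int], cr_cols: list[int], planted: set[int],
    min_valid: int = 2,
) -> None:
    """Restore one value so no background feature mimics a planted CR/CS_only."""
    n_cs = (~missing[:, cs_cols]).sum(axis=1)
    n_cr = (~missing[:, cr_cols]).sum(axis=1)
    for i in np.nonzero((n_cr >= min_valid) & (n_cs == 0))[0]:
        if i not in planted:
            missing[i, cs_cols[0]] = False
    for i in np.nonzero((n_cs >= min_valid) & (n_cr == 0))[0]:
        if i not in planted:
            missing[i, cr_cols[0]] = False


def _generate_phospho(config, design, protein_ids, gene_symbols, parent_signal,
                      parent_realized, log10_base):
    rng = _rng(config.seed, "phospho")
    samples = design.samples
    m, s = config.n_sites, len(samples)
    parents = rng.integers(0, len(protein_ids), size=m)
    residues = rng.choice(list("SSSTTY"), size=m)  # S most common, Y rare
    positions = rng.integers(1, 1200, size=m)
    site_ids = []
    seen = set()
    for j in range(m):
        while True:
            sid = f"{protein_ids[parents[j]]}_{residues[j]}{positions[j]}"
            if sid not in seen:
                break
            positions[j] = rng.integers(1, 5000)
        seen.add(sid)
        site_ids.append(sid)

    w = config.site_parent_weight
    own = rng.normal(0.0, config.baseline_sd, size=m)[:, None] + rng.normal(
        0.0, config.noise_sd, size=(m, s)
    )

    cs_line, cr_lines = design.cs_line, design.cr_lines
    col_of_line = {
        ln: [samples.index(x) for x in design.samples_for_line(ln)]
        for ln in design.cell_lines
    }
    cs_cols = col_of_line[cs_line]
    cr_cols = [c for ln in cr_lines for c in col_of_line[ln]]
    ben_cols = col_of_line[design.reference_line]

    # planted site blocks: disjoint index slices of a shuffled order
    order = list(rng.permutation(m))
    blocks: dict[str, list[int]] = {}

    def take(name: str, k: int) -> None:
        blocks[name] = order[:k]
        del order[:k]

    take("sites_CR_up", config.n_sites_cr_de // 2)
    take("sites_CR_down", config.n_sites_cr_de - config.n_sites_cr_de // 2)
    take("sites_CR_only", config.n_cr_only_sites)
    take("sites_CS_only", config.n_cs_only_sites)
    for k in range(config.n_kinases):
        take(f"kinase_{k:02d}", config.substrates_per_kinase)

    e = config.de_effect_log2
    site_shift = np.zeros((m, s))
    for rows, delta in ((blocks["sites_CR_up"], +e / 2), (blocks["sites_CR_down"], -e / 2)):
        for c_ln in cr_lines:
            site_shift[np.ix_(rows, col_of_line[c_ln])] += delta
        site_shift[np.ix_(rows, cs_cols)] -= delta

    kinase_names = [f"K{k:02d}" for k in range(config.n_kinases)]
    active_kinase = kinase_names[0] if kinase_names else ""
    ks_map = {
        kn: [site_ids[j] for j in blocks[f"kinase_{k:02d}"]]
        for k, kn in enumerate(kinase_names)
    }
    if active_kinase:
        rows = blocks["kinase_00"]
        for c_ln in cr_lines:
            site_shift[np.ix_(rows, col_of_line[c_ln])] += config.kinase_effect_log2

    site_signal = w * parent_signal[parents, :] + site_shift
    log2_site = w * parent_realized[parents, :] + np.sqrt(1 - w**2) * own + site_shift

    # dropout: logistic in parent abundance, one extra order of difficulty
    floor = config.ibaq_center_log10 - config.dynamic_orders / 2
    depth = log10_base[parents] - floor - config.phospho_extra_orders
    p_drop = 1.0 / (1.0 + np.exp((depth - config.dropout_mid_orders) / config.dropout_scale_orders))
    missing = rng.random((m, s)) < p_drop[:, None]
    missing |= rng.random((m, s)) < config.uniform_dropout

    protected = (
        blocks["sites_CR_up"] + blocks["sites_CR_down"]
        + [j for k in range(config.n_kinases) for j in blocks[f"kinase_{k:02d}"]]
    )
    missing[protected, :] = False
    for j in blocks["sites_CR_only"]:
        missing[j, :] = False
        missing[j, cs_cols] = True
        missing[j, ben_cols] = True
    for j in blocks["sites_CS_only"]:
        missing[j, :] = False
        missing[j, cr_cols] = True
        missing[j, ben_cols] = True
    planted_pa = set(blocks["sites_CR_only"]) | set(blocks["sites_CS_only"])
    _guard_presence_absence(missing, cs_cols, cr_cols, planted_pa)

    ratios = pd.DataFrame(np.exp2(log2_site), index=site_ids, columns=samples).mask(missing)
    genes = pd.Series(
        [gene_symbols[protein_ids[p]] for p in parents], index=site_ids, name="gene_symbols"
    )
    table = FeatureTable(ratios=ratios, design=design, layer=PHOSPHO, gene_symbols=genes)

    site_blocks = {
        name: sorted(site_ids[j] for j in blocks[name])
        for name in ("sites_CR_up", "sites_CR_down", "sites_CR_only", "sites_CS_only")
    }
    site_blocks.update(
        _effective_truth(site_signal, site_ids, design, col_of_line, prefix="sites_")
    )
    return table, site_blocks, ks_map, active_kinase


# ---------------------------------------------------------------------------
# auxiliary resources for downstream stages


def make_gene_sets(truth: GroundTruth, config: SyntheticConfig) -> dict[str, list[str]]:
    """GMT-style collection: the planted modules plus two annotation terms
    built around the resistance blocks (so over-representation of the CR
    marker lists has a recoverable signal), padded with random genes."""
    rng = _rng(config.seed, "gene-sets")
    sets = {name: list(genes) for name, genes in truth.modules.items()}
    universe = sorted(truth.protein_gene.values())
    for term, block in (("CR_UP_PROGRAM", "CR_up"), ("CR_DOWN_PROGRAM", "CR_down")):
        core = [truth.protein_gene[p] for p in truth.blocks[block]]
        pad = [g for g in rng.choice(universe, size=len(core), replace=False) if g not in core]
        sets[term] = sorted(core + pad)
    return sets


def make_complexes(truth: GroundTruth, config: SyntheticConfig) -> dict[str, list[str]]:
    """Synthetic complex membership: random cliques over the gene universe,
    with a few complexes seeded from the planted CR biomarkers so the
    biomarker subgraph is non-trivial."""
    rng = _rng(config.seed, "complexes")
    genes = sorted(truth.protein_gene.values())
    lo, hi = config.complex_size_range
    out: dict[str, list[str]] = {}
    for c in range(config.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        out[f"CPX{c:04d}"] = sorted(rng.choice(genes, size=size, replace=False))
    biomarkers = sorted(
        truth.protein_gene[p]
        for name in ("CR_up", "CR_down", "CR_only", "CS_only")
        for p in truth.blocks[name]
    )
    for c in range(10):
        size = int(rng.integers(lo, hi + 1))
        out[f"CPXB{c:03d}"] = sorted(rng.choice(biomarkers, size=min(size, len(biomarkers)),
                                                replace=False))
    return out


def write_maxquant_tables(
    proteome: FeatureTable, phospho: FeatureTable, config: SyntheticConfig, prefix
) -> tuple[str, str]:
    """Serialize the pair as MaxQuant-dialect TSVs, artifact rows included.

    Contaminant / reverse / only-identified-by-site decoys are prepended so
    the ingest filters have something to remove; phospho ratios are written
    under multiplicity ``___1`` (with near-empty ``___2``) to exercise the
    collapse rule. Returns the two file paths.
    """
    rng = _rng(config.seed, "artifact-rows")
    samples = proteome.design.samples

    prot = pd.DataFrame({"Majority protein IDs": proteome.feature_ids})
    prot["Gene names"] = proteome.gene_symbols.to_numpy()
    prot["Potential contaminant"] = ""
    prot["Reverse"] = ""
    prot["Only identified by site"] = ""
    for s_ in samples:
        prot[f"Ratio H/L normalized {s_}"] = proteome.ratios[s_].fillna(0).to_numpy()
        prot[f"iBAQ {s_}"] = proteome.ibaq[s_].fillna(0).to_numpy()

    decoys = []
    specs = [("CON__%04d", config.n_contaminants, "Potential contaminant"),
             ("REV__%04d", config.n_reverse, "Reverse"),
             ("OIS__%04d", config.n_only_by_site, "Only identified by site")]
    for pattern, count, column in specs:
        for i in range(count):
            row = {"Majority protein IDs": pattern % i, "Gene names": pattern % i,
                   "Potential contaminant": "", "Reverse": "", "Only identified by site": ""}
            row[column] = "+"
            for s_ in samples:
                row[f"Ratio H/L normalized {s_}"] = float(np.round(rng.lognormal(0, 0.5), 6))
                row[f"iBAQ {s_}"] = float(np.round(rng.lognormal(14, 1), 3))
            decoys.append(row)
    prot_out = pd.concat([pd.DataFrame(decoys), prot], ignore_index=True)
    prot_path = f"{prefix}_proteinGroups.txt"
    prot_out.to_csv(prot_path, sep="\t", index=False, float_format="%.17g")

    accs, residues, positions = [], [], []
    for sid in phospho.feature_ids:
        acc, _, tail = sid.rpartition("_")
        accs.append(acc)
        residues.append(tail[0])
        positions.append(int(tail[1:]))
    phos = pd.DataFrame({"Protein": accs, "Amino acid": residues, "Position": positions})
    phos["Gene names"] = phospho.gene_symbols.to_numpy()
    phos["Localization prob"] = np.round(rng.uniform(0.7, 1.0, size=len(phos)), 4)
    phos["Potential contaminant"] = ""
    phos["Reverse"] = ""
    for s_ in samples:
        phos[f"Ratio H/L normalized {s_}___1"] = phospho.ratios[s_].fillna(0).to_numpy()
        phos[f"Ratio H/L normalized {s_}___2"] = 0.0
        phos[f"Ratio H/L normalized {s_}___3"] = 0.0
    phos_path = f"{prefix}_PhosphoSTYSites.txt"
    phos.to_csv(phos_path, sep="\t", index=False, float_format="%.17g")
    return prot_path, phos_path


# ---------------------------------------------------------------------------
# recovery scoring


def set_metrics(predicted: list[str], truth: list[str]) -> dict[str, float]:
    """Precision, recall and realized FDR of a predicted feature list."""
    pred, true = set(predicted), set(truth)
    tp = len(pred & true)
    precision = tp / len(pred) if pred else (1.0 if not true else 0.0)
    recall = tp / len(true) if true else 1.0
    return {"precision": precision, "recall": recall, "fdr": 1.0 - precision,
            "n_predicted": len(pred), "n_true": len(true), "tp": tp}


def evaluate(
    truth: GroundTruth,
    protein_sets=None,
    phospho_sets=None,
    kinase_table: pd.DataFrame | None = None,
    module_table: pd.DataFrame | None = None,
) -> dict:
    """Score recovered biomarker sets, kinase ranks and module overdispersion
    against the planted truth. Any argument may be omitted."""
    report: dict = {}
    if protein_sets is not None:
        for label, pred, eff_key, core_key in (
            ("protein_CR_up", protein_sets.cr_up, "true_CR_up", "CR_up"),
            ("protein_CR_down", protein_sets.cr_down, "true_CR_down", "CR_down"),
            ("protein_CR_only", protein_sets.cr_only, "CR_only", "CR_only"),
            ("protein_CS_only", protein_sets.cs_only, "CS_only", "CS_only"),
            ("protein_common_up", protein_sets.common_up, "true_common_up", "common_up"),
            ("protein_common_down", protein_sets.common_down, "true_common_down", "common_down"),
        ):
            metrics = set_metrics(pred, truth.blocks[eff_key])
            metrics["recall_planted"] = set_metrics(pred, truth.blocks[core_key])["recall"]
            report[label] = metrics
    if phospho_sets is not None:
        for label, pred, eff_key, core_key in (
            ("site_CR_up", phospho_sets.cr_up, "true_sites_CR_up", "sites_CR_up"),
            ("site_CR_down", phospho_sets.cr_down, "true_sites_CR_down", "sites_CR_down"),
            ("site_CR_only", phospho_sets.cr_only, "sites_CR_only", "sites_CR_only"),
            ("site_CS_only", phospho_sets.cs_only, "sites_CS_only", "sites_CS_only"),
        ):
            metrics = set_metrics(pred, truth.blocks[eff_key])
            metrics["recall_planted"] = set_metrics(pred, truth.blocks[core_key])["recall"]
            report[label] = metrics
    if kinase_table is not None and len(kinase_table):
        ranked = kinase_table.sort_values("z", ascending=False, kind="stable")
        kin = list(ranked["kinase"])
        report["active_kinase_rank"] = (
            kin.index(truth.active_kinase) + 1 if truth.active_kinase in kin else None
        )
    if module_table is not None and len(module_table):
        row = module_table[module_table["module"] == truth.overdispersed_module]
        report["overdispersed_module_p"] = (
            float(row["p_overdispersion"].iloc[0]) if len(row) else None
        )
    return report
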