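"""Immune-cell signature compendium: loading, composite labels, lineage filtering.

The compendium maps genes to the immune cell type whose infiltration their
expression marks, each cell type carrying an innate/adaptive class.  Before a
compendium built from sorted immune cells can be used on bulk tumor
expression, genes that the tumor lineage itself expresses highly must be
removed, otherwise tumor-intrinsic expression masquerades as infiltration.
Here that filter removes any gene ranking in the top quartile of a
melanoma/melanocyte reference transcriptome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCompendium",
    "LineageProfile",
    "FilterConfig",
    "CompositeRule",
    "DEFAULT_COMPOSITE_RULES",
    "CONTROL_TISSUE_LABELS",
    "INNATE_TYPES",
    "ADAPTIVE_TYPES",
    "load_compendium",
    "derive_composite_labels",
    "drop_labels",
    "filter_lineage_expressed",
    "read_compendium_tsv",
    "write_compendium_tsv",
    "read_compendium_gmt",
    "write_compendium_gmt",
    "read_lineage_profile_tsv",
]

#: Cell types counted toward the innate immune score.
INNATE_TYPES = (
    "NK", "NKb", "NKd", "DC", "aDC", "iDC", "pDC",
    "Mast cells", "Macrophages", "Eosinophils", "Neutrophils",
)
#: Cell types counted toward the adaptive immune score.
ADAPTIVE_TYPES = (
    "B cells", "T cells", "CD8 T cells", "Cytotoxic cells", "Th", "Tfh",
    "Th1", "Th2", "Th17", "Treg", "Tcm", "Tem", "Tgd",
)

#: Control-tissue labels present in FACS-derived compendia that are dropped
#: before lineage filtering (they mark non-immune reference tissues).
CONTROL_TISSUE_LABELS = ("SW480 cancer cells", "Normal mucosa", "Blood vessels", "Lymph vessels")


@dataclass(frozen=True)
class CompositeRule:
    """Relabel a gene to ``label`` when it is listed under enough of ``members``.

    ``min_count=None`` requires membership in *all* member subtypes.
    """

    label: str
    members: tuple
    immunity: str
    min_count: int | None = None

    def required(self) -> int:
        return len(self.members) if self.min_count is None else self.min_count


#: Broader-phenotype rules: genes shared by both NK subtypes mark generic NK
#: cells; genes shared by every cytolytic subtype mark cytotoxic cells; genes
#: shared by two or more helper/memory/CD8 subtypes mark generic T cells.
DEFAULT_COMPOSITE_RULES = (
    CompositeRule("Cytotoxic cells", ("NKb", "NKd", "CD8 T cells", "Tgd"), "adaptive"),
    CompositeRule("NK", ("NKb", "NKd"), "innate"),
    CompositeRule("T cells", ("Th1", "Th2", "CD8 T cells", "Tem", "Tcm"), "adaptive", min_count=2),
)


class SignatureCompendium:
    """Deduplicated (gene, cell type) membership with per-type immunity class.

    ``cell_types`` preserves first-appearance order of the input table so
    downstream tables have a stable column order.
    """

    def __init__(self, entries, immunity_class) -> None:
        seen = set()
        ordered = []
        types = []
        for gene, label in entries:
            key = (str(gene), str(label))
            if key in seen:
                continue
            seen.add(key)
            ordered.append(key)
            if key[1] not in types:
                types.append(key[1])
        if not ordered:
            raise ValueError("empty signature table")
        missing = [t for t in types if t not in immunity_class]
        if missing:
            raise ValueError(f"immunity class missing for cell type(s): {missing}")
        self._entries = tuple(ordered)
        self.cell_types = tuple(types)
        self.immunity_class = {t: immunity_class[t] for t in types}

    @property
    def entries(self):
        return self._entries

    @property
    def genes(self) -> tuple:
        out, seen = [], set()
        for g, _ in self._entries:
            if g not in seen:
                seen.add(g)
                out.append(g)
        return tuple(out)

    def labels_of(self, gene: str) -> tuple:
        return tuple(t for g, t in self._entries if g == gene)

    def genes_for(self, label: str) -> tuple:
        return tuple(g for g, t in self._entries if t == label)

    def gene_sets(self) -> dict:
        sets: dict = {t: [] for t in self.cell_types}
        for g, t in self._entries:
            sets[t].append(g)
        return {t: tuple(gs) for t, gs in sets.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, t, self.immunity_class[t]) for g, t in self._entries],
            columns=["gene", "cell_type", "immunity_class"],
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignatureCompendium)
            and set(self._entries) == set(other._entries)
            and self.immunity_class == other.immunity_class
        )


@dataclass(frozen=True)
class LineageProfile:
    """Whole-transcriptome expression of one tumor-lineage reference."""

    name: str
    expression: pd.Series

    def __post_init__(self) -> None:
        vals = self.expression.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"lineage profile {self.name!r} has non-finite values")


@dataclass(frozen=True)
class FilterConfig:
    """Lineage-expression filter: remove genes ranked in the top ``top_fraction``.

    ``rule='any'`` removes a gene highly expressed in at least one reference;
    ``'all'`` requires every reference.
    """

    top_fraction: float = 0.25
    rule: str = "any"

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.rule not in ("any", "all"):
            raise ValueError("rule must be 'any' or 'all'")


def load_compendium(table) -> SignatureCompendium:
    """Build a compendium from rows of (gene, cell_type, immunity_class).

    ``table`` may be a DataFrame with those columns or an iterable of
    3-tuples.  Duplicate rows are collapsed; a cell type appearing with two
    different immunity classes is an error.
    """
    if isinstance(table, pd.DataFrame):
        rows = table[["gene", "cell_type", "immunity_class"]].itertuples(index=False)
    else:
        rows = table
    entries = []
    classes: dict = {}
    for gene, cell_type, imm in rows:
        imm = str(imm)
        if imm not in ("innate", "adaptive", "unclassified"):
            raise ValueError(f"unknown immunity class {imm!r} for {cell_type!r}")
        if cell_type in classes and classes[cell_type] != imm:
            raise ValueError(
                f"conflicting immunity class for cell type {cell_type!r}: "
                f"{classes[cell_type]!r} vs {imm!r}"
            )
        classes[cell_type] = imm
        entries.append((gene, cell_type))
    if not entries:
        raise ValueError("empty signature table")
    return SignatureCompendium(entries, classes)


def derive_composite_labels(
    comp: SignatureCompendium, rules=DEFAULT_COMPOSITE_RULES
) -> SignatureCompendium:
    """Relabel genes shared across configured subtype sets to composite labels.

    Rules are applied in order; a relabeled gene loses its member-subtype
    entries, so earlier (more specific) rules take precedence.  Idempotent:
    composite labels never appear among rule members.
    """
    entries = list(comp.entries)
    classes = dict(comp.immunity_class)
    # labels legitimately consumed by an earlier rule (or a previous
    # application, recognizable by the composite label's presence) are
    # tolerated; only labels foreign to the compendium are an error
    known = set(comp.cell_types)
    for rule in rules:
        unknown = [m for m in rule.members if m not in known]
        if unknown and rule.label not in known:
            raise ValueError(f"composite rule {rule.label!r} references unknown subtype(s) {unknown}")
        known.add(rule.label)
        members = set(rule.members) - set(unknown)
        by_gene: dict = {}
        for g, t in entries:
            if t in members:
                by_gene.setdefault(g, set()).add(t)
        hits = {g for g, ts in by_gene.items() if len(ts) >= rule.required()}
        if not hits:
            continue
        entries = [(g, t) for g, t in entries if not (g in hits and t in members)]
        entries.extend((g, rule.label) for g in sorted(hits))
        classes.setdefault(rule.label, rule.immunity)
    remaining = {t for _, t in entries}
    classes = {t: c for t, c in classes.items() if t in remaining}
    return SignatureCompendium(entries, classes)


def drop_labels(comp: SignatureCompendium, blocklist=CONTROL_TISSUE_LABELS) -> SignatureCompendium:
    """Remove every entry whose cell-type label is in ``blocklist``."""
    block = set(blocklist)
    entries = [(g, t) for g, t in comp.entries if t not in block]
    if not entries:
        raise ValueError("blocklist removed every entry")
    classes = {t: c for t, c in comp.immunity_class.items() if t not in block}
    return SignatureCompendium(entries, classes)


def filter_lineage_expressed(
    comp: SignatureCompendium,
    profiles,
    cfg: FilterConfig = FilterConfig(),
) -> SignatureCompendium:
    """Drop compendium genes highly expressed in tumor-lineage references.

    A gene counts as highly expressed in a profile when its descending rank
    (ties share the best rank, so boundary ties are all removed) falls within
    the top ``cfg.top_fraction`` of that profile's genes.  Symbols are matched
    case-insensitively; a compendium gene absent from a profile counts as not
    highly expressed there.  Cell types left with no genes are dropped with a
    warning.
    """
    profiles = list(profiles)
    if not profiles:
        warnings.warn("no lineage profiles supplied; compendium unchanged", stacklevel=2)
        return comp

    comp_genes = comp.genes
    upper = {g.upper() for g in comp_genes}
    high_flags = {g: [] for g in comp_genes}
    for prof in profiles:
        expr = prof.expression.copy()
        expr.index = expr.index.map(lambda s: str(s).upper())
        expr = expr[~expr.index.duplicated(keep="first")]
        missing = upper - set(expr.index)
        if len(missing) > 0.10 * len(comp_genes):
            raise ValueError(
                f"profile {prof.name!r} is missing {len(missing)}/{len(comp_genes)} "
                "compendium genes (>10%); not a whole-genome reference?"
            )
        # min-rank on descending values: rank 1 = highest; ties share the best
        # rank so every gene tied at the boundary is treated as highly expressed
        ranks = expr.rank(ascending=False, method="min")
        n_prof = len(expr)
        top = set(ranks.index[ranks <= cfg.top_fraction * n_prof])
        for g in comp_genes:
            if g.upper() in expr.index:
                high_flags[g].append(g.upper() in top)

    def is_high(flags) -> bool:
        if not flags:
            return False
        return any(flags) if cfg.rule == "any" else all(flags)

    removed = {g for g, flags in high_flags.items() if is_high(flags)}
    entries = [(g, t) for g, t in comp.entries if g not in removed]
    if not entries:
        raise ValueError("lineage filtering removed every gene")
    kept_types = {t for _, t in entries}
    lost = [t for t in comp.cell_types if t not in kept_types]
    if lost:
        warnings.warn(f"cell type(s) left with no genes after filtering: {lost}", stacklevel=2)
    classes = {t: c for t, c in comp.immunity_class.items() if t in kept_types}
    logger.info("lineage filter removed %d/%d genes", len(removed), len(comp_genes))
    return SignatureCompendium(entries, classes)


# ---------------------------------------------------------------------------
# I/O: 3-column TSV and GMT (immunity class in the description field)

def read_compendium_tsv(path) -> SignatureCompendium:
    df = pd.read_csv(path, sep="\t")
    return load_compendium(df)


def write_compendium_tsv(comp: SignatureCompendium, path) -> None:
    comp.to_frame().to_csv(path, sep="\t", index=False)


def read_compendium_gmt(path) -> SignatureCompendium:
    """Read one gene set per cell type; description holds ``class|...`` fields."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            label, desc = fields[0], fields[1]
            imm = desc.split("|")[0] if desc else "unclassified"
            for gene in fields[2:]:
                if gene:
                    rows.append((gene, label, imm))
    return load_compendium(rows)


def write_compendium_gmt(comp: SignatureCompendium, path) -> None:
    with open(path, "w") as fh:
        for label, genes in comp.gene_sets().items():
            desc = f"{comp.immunity_class[label]}|melimmune"
            fh.write("\t".join([label, desc, *genes]) + "\n")


def read_lineage_profile_tsv(path, name=None) -> LineageProfile:
    """Read a 2-column (gene, value) TSV as one lineage reference profile."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "value"], comment="#")
    # tolerate a header row
    if not np.issubdtype(np.asarray(pd.to_numeric(df["value"], errors="coerce")).dtype, np.number):
        raise ValueError("second column must be numeric")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        df = df[vals.notna()]
        vals = vals[vals.notna()]
    series = pd.Series(vals.to_numpy(dtype=float), index=df["gene"].astype(str).to_numpy())
    return LineageProfile(name=str(name or path), expression=series)
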