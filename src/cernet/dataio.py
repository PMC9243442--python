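"""Readers and writers for the pipeline's tabular formats.

All matrices travel as TSV: first column ``feature_id``, header row of sample
ids, decimal-point numbers only, no thousands separators. ``NA`` is rejected
inside matrices. Gene sets use the standard GMT dialect. Validation is strict:
malformed input raises :class:`FormatError` naming the offending row/column
rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("cernet")

EXPRESSION_LAYERS = ("mRNA", "miRNA", "lncRNA")
LAYERS = EXPRESSION_LAYERS + ("methylation",)
TARGET_LAYERS = ("mRNA", "lncRNA")
GROUPS = ("case", "control")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("chrX", "chrY", "chrM", "unknown")
SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix with a molecular-layer tag.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids as
    columns. Expression layers hold log2 intensities; the methylation layer
    holds beta values constrained to [0, 1].
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise FormatError("empty matrix")
        if self.values.isna().any().any():
            cell = _first_bad_cell(self.values, self.values.isna())
            raise FormatError(f"missing value at feature {cell[0]!r}, sample {cell[1]!r}")
        if self.layer == "methylation":
            bad = (self.values < 0) | (self.values > 1)
            if bad.any().any():
                r, c = _first_bad_cell(self.values, bad)
                raise FormatError(
                    f"beta value out of [0, 1] at feature {r!r}, sample {c!r}: "
                    f"{self.values.at[r, c]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        keep = [f for f in self.feature_ids if f in set(ids)]
        return ExpressionMatrix(self.values.loc[keep], self.layer)


def _first_bad_cell(df: pd.DataFrame, mask: pd.DataFrame):
    stacked = mask.stack()
    idx = stacked[stacked].index[0]
    return idx[0], idx[1]


@dataclass
class SampleSheet:
    """Sample -> group assignment, with optional tissue pairing.

    ``table`` columns: sample_id, group (case/control), pair_id (may be all
    None for unpaired cohorts; for reference data pair_id links the two
    tissues of one donor).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if "pair_id" not in self.table.columns:
            self.table = self.table.assign(pair_id=None)
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in sample sheet: {dups}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def require_two_per_group(self) -> None:
        for g in GROUPS:
            n = len(self.samples_in(g))
            if n < 2:
                raise FormatError(f"group {g!r} has {n} samples; need at least 2")

    def pairs(self) -> list[tuple[str, str]]:
        """(case_sample, control_sample) per pair_id, for paired designs."""
        t = self.table.dropna(subset=["pair_id"])
        out = []
        for pid, sub in t.groupby("pair_id", sort=True):
            cases = sub.loc[sub["group"] == "case", "sample_id"].tolist()
            ctrls = sub.loc[sub["group"] == "control", "sample_id"].tolist()
            if len(cases) != 1 or len(ctrls) != 1:
                raise FormatError(
                    f"pair {pid!r} must map exactly one case and one control sample"
                )
            out.append((cases[0], ctrls[0]))
        return out


@dataclass
class FeatureAnnotation:
    """feature_id -> (chromosome, layer), with a closed chromosome vocabulary."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature_id", "chromosome", "layer"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if self.table["feature_id"].duplicated().any():
            dups = self.table.loc[self.table["feature_id"].duplicated(), "feature_id"].tolist()
            raise FormatError(f"duplicate annotated features: {dups}")
        bad = set(self.table["chromosome"]) - set(CHROMOSOMES)
        if bad:
            raise FormatError(f"unknown chromosomes: {sorted(bad)}")

    def chromosome_of(self, feature_id: str) -> str:
        hit = self.table.loc[self.table["feature_id"] == feature_id, "chromosome"]
        return hit.iloc[0] if len(hit) else "unknown"

    def chromosome_map(self) -> dict[str, str]:
        return dict(zip(self.table["feature_id"], self.table["chromosome"]))


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TargetPredictionTable:
    """miRNA -> target predictions with a source-count column.

    Emulates exports from sequence-based prediction databases; ``n_sources``
    counts how many programs support the pair.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna_id", "target_id", "target_layer", "n_sources"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"prediction table missing columns: {sorted(missing)}")
        bad = set(self.table["target_layer"]) - set(TARGET_LAYERS)
        if bad:
            raise FormatError(f"unknown target_layer values: {sorted(bad)}")
        if (self.table["n_sources"] < 1).any():
            raise FormatError("n_sources must be >= 1")
        if self.table.duplicated(subset=["mirna_id", "target_id"]).any():
            dups = self.table.loc[
                self.table.duplicated(subset=["mirna_id", "target_id"]),
                ["mirna_id", "target_id"],
            ]
            raise FormatError(f"duplicate prediction pairs: {dups.values.tolist()}")

    def pairs(self, target_layer: str | None = None) -> set[tuple[str, str]]:
        t = self.table
        if target_layer is not None:
            t = t[t["target_layer"] == target_layer]
        return set(zip(t["mirna_id"], t["target_id"]))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers


def read_expression_matrix(path, layer: str) -> ExpressionMatrix:
    """Read a TSV matrix (first column feature_id, header of sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = _first_bad_cell(df, bad)
        raise FormatError(
            f"{path}: non-numeric value at feature {r!r}, sample {c!r}: {df.at[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = _first_bad_cell(numeric, numeric.isna())
        raise FormatError(f"{path}: missing value at feature {r!r}, sample {c!r}")
    # astype(float) round-trips shortest reprs exactly; to_numeric may not
    out = df.astype(float)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return ExpressionMatrix(out, layer)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].where(df["pair_id"].notna(), None)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path) -> FeatureAnnotation:
    return FeatureAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annotation: FeatureAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member [TAB member ...].

    Duplicate members within one line are deduplicated with a logged warning;
    a line with fewer than three fields is a format error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.warning(
                        "gene set %s (line %d): duplicate member %s deduplicated",
                        name, lineno, m,
                    )
                seen[m] = None
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            sets[name] = (desc, list(seen))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_target_predictions(path, min_sources: int = 1) -> TargetPredictionTable:
    """Read a prediction TSV; rows supported by fewer than ``min_sources``
    programs are dropped (count logged)."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str,
                                            "target_layer": str, "n_sources": int})
    table = TargetPredictionTable(df)
    if min_sources > 1:
        kept = df[df["n_sources"] >= min_sources].reset_index(drop=True)
        n_dropped = len(df) - len(kept)
        if n_dropped:
            logger.info("dropped %d prediction rows with n_sources < %d",
                        n_dropped, min_sources)
        table = TargetPredictionTable(kept)
    return table


def write_target_predictions(table: TargetPredictionTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_edge_list(edges, path) -> None:
    """Write correlation pairs / triad edges as a TSV edge list.

    Ordering is stable — |r| descending, then source, then target — so
    repeated runs on identical inputs produce byte-identical files.
    """
    header = ["source", "target", "edge_type", "r", "p", "fdr", "predicted_support"]
    rows = []
    for e in edges:
        rows.append((e.source_id, e.target_id, e.pair_type, e.r, e.p, e.fdr,
                     str(bool(e.predicted)).lower()))
    rows.sort(key=lambda t: (-abs(t[3]), t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(
                [r[0], r[1], r[2], repr(float(r[3])), repr(float(r[4])),
                 repr(float(r[5])), r[6]]) + "\n")
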