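"""Reading, validation and preprocessing of MZ twin panel tables.

The canonical wide layout has one row per monozygotic pair: three traits
(``mp`` maladaptive parenting, ``ep`` emotional problems, ``bp`` behavioural
problems) measured at three occasions (ages 9, 12 and 16) on both twins,
plus the pair's sex and wave-specific ages.  Default columns::

    pair_id, sex, age9, age12, age16, {mp,ep,bp}{9,12,16}_t{1,2}

Preprocessing mirrors the analysis pipeline: twin age and sex are regressed
out of every trait variable at the individual level and the unstandardised
residuals are carried forward; twin-difference scores (twin 1 - twin 2) are
derived for the difference-score model variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem import ObservedMatrix

TRAITS = ("mp", "ep", "bp")
OCCASIONS = (9, 12, 16)

__all__ = [
    "TwinPanelTable", "DiffScoreTable", "Schema",
    "read_twin_panel", "write_twin_panel", "residualize_covariates",
    "make_difference_scores", "to_observed_matrix",
    "trait_columns", "pair_manifest", "individual_manifest",
]


def trait_columns(traits=TRAITS, occasions=OCCASIONS):
    """Per-twin trait column stems in canonical order (occasion-major)."""
    return [f"{v}{t}" for t in occasions for v in traits]


def pair_manifest(traits=TRAITS, occasions=OCCASIONS) -> list[str]:
    """Pair-level observed-variable order: twin 1's nine variables, then
    twin 2's."""
    stems = trait_columns(traits, occasions)
    return [f"{s}_t1" for s in stems] + [f"{s}_t2" for s in stems]


def individual_manifest(traits=TRAITS, occasions=OCCASIONS) -> list[str]:
    return trait_columns(traits, occasions)


@dataclass
class Schema:
    """Column mapping and parsing options for delimited twin-panel files."""

    traits: tuple[str, ...] = TRAITS
    occasions: tuple[int, ...] = OCCASIONS
    pair_id: str = "pair_id"
    sex: str | tuple[str, str] = "sex"        # one column, or per-twin pair
    age: dict[int, str] = field(default_factory=lambda: {t: f"age{t}" for t in OCCASIONS})
    sep: str = ","
    missing: tuple[str, ...] = ("", "NA", "nan", "NaN")

    def value_column(self, trait: str, occ: int, twin: int) -> str:
        return f"{trait}{occ}_t{twin}"

    def value_columns(self) -> list[str]:
        return [self.value_column(v, t, j)
                for j in (1, 2) for t in self.occasions for v in self.traits]


@dataclass
class TwinPanelTable:
    """Validated pair-level panel: trait scores, covariates, missingness."""

    frame: pd.DataFrame
    schema: Schema = field(default_factory=Schema)
    residualized: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def pair_ids(self) -> np.ndarray:
        return self.frame[self.schema.pair_id].to_numpy()

    def value(self, trait: str, occ: int, twin: int) -> pd.Series:
        return self.frame[self.schema.value_column(trait, occ, twin)]

    def copy(self) -> "TwinPanelTable":
        return TwinPanelTable(self.frame.copy(), self.schema, self.residualized)


@dataclass
class DiffScoreTable:
    """Within-pair difference scores d[v,t] = twin1 - twin2 (NaN if either
    twin is missing)."""

    frame: pd.DataFrame
    traits: tuple[str, ...] = TRAITS
    occasions: tuple[int, ...] = OCCASIONS

    @property
    def n_pairs(self) -> int:
        return len(self.frame)


class TwinDataError(ValueError):
    """Raised when a twin panel violates its structural invariants."""


# ---------------------------------------------------------------------------
# reading / validation
# ---------------------------------------------------------------------------

def read_twin_panel(path, schema: Schema | None = None) -> TwinPanelTable:
    """Read and validate a delimited twin panel file.

    Raises :class:`TwinDataError` on duplicate pair identifiers or on
    within-pair sex discordance (which would contradict monozygosity);
    rows whose pair identifier cannot be parsed are rejected with a report.
    """
    schema = schema or Schema()
    raw = pd.read_csv(path, sep=schema.sep, na_values=list(schema.missing),
                      keep_default_na=True, dtype={schema.pair_id: str})
    return validate_twin_panel(raw, schema)


def validate_twin_panel(raw: pd.DataFrame, schema: Schema | None = None) -> TwinPanelTable:
    schema = schema or Schema()
    required = [schema.pair_id] + list(schema.age.values()) + schema.value_columns()
    sex_cols = [schema.sex] if isinstance(schema.sex, str) else list(schema.sex)
    required += sex_cols
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise TwinDataError(f"missing required columns: {missing_cols}")

    frame = raw.copy()
    pid = frame[schema.pair_id].astype("string")
    bad = pid.isna() | (pid.str.strip() == "")
    if bad.any():
        n_bad = int(bad.sum())
        frame = frame[~bad].copy()
        frame.attrs["rejected_rows"] = n_bad
    dup = frame[schema.pair_id][frame[schema.pair_id].duplicated()]
    if len(dup):
        raise TwinDataError(
            f"duplicate pair_id values: {sorted(set(dup.astype(str)))}")

    for col in schema.value_columns() + list(schema.age.values()) + sex_cols:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")

    if len(sex_cols) == 2:
        s1, s2 = frame[sex_cols[0]], frame[sex_cols[1]]
        both = s1.notna() & s2.notna()
        disc = both & (s1 != s2)
        if disc.any():
            pairs = frame.loc[disc, schema.pair_id].astype(str).tolist()
            raise TwinDataError(
                f"sex discordant within pair (MZ assumption violated): {pairs}")
        frame["sex"] = s1.where(s1.notna(), s2)
        schema = Schema(**{**schema.__dict__, "sex": "sex"})

    frame = frame.reset_index(drop=True)
    return TwinPanelTable(frame, schema)


def write_twin_panel(table: TwinPanelTable, path) -> None:
    """Write the table back out in its schema's delimited layout."""
    schema = table.schema
    sex_cols = [schema.sex] if isinstance(schema.sex, str) else list(schema.sex)
    cols = ([schema.pair_id] + sex_cols + list(schema.age.values())
            + schema.value_columns())
    table.frame[cols].to_csv(path, sep=schema.sep, index=False)


# ---------------------------------------------------------------------------
# residualisation
# ---------------------------------------------------------------------------

def residualize_covariates(table: TwinPanelTable,
                           covariates: tuple[str, ...] = ("age", "sex")) -> TwinPanelTable:
    """Regress wave-appropriate age and sex out of every trait variable.

    Both twins are pooled at the individual level; each trait-by-wave
    variable is replaced by its unstandardised OLS residual on an intercept
    plus the requested covariates.  Missing trait values stay missing, and
    individuals missing a covariate get a missing residual.
    """
    schema = table.schema
    out = table.frame.copy()
    sex = out[schema.sex] if isinstance(schema.sex, str) else out[schema.sex[0]]
    for occ in schema.occasions:
        age = out[schema.age[occ]]
        for trait in schema.traits:
            cols = [schema.value_column(trait, occ, j) for j in (1, 2)]
            y = pd.concat([out[c] for c in cols], ignore_index=True)
            design_parts = []
            if "age" in covariates:
                design_parts.append(pd.concat([age, age], ignore_index=True))
            if "sex" in covariates:
                design_parts.append(pd.concat([sex, sex], ignore_index=True))
            resid = _ols_residuals(y, design_parts, f"{trait}{occ}")
            n = len(out)
            out[cols[0]] = resid[:n].to_numpy()
            out[cols[1]] = resid[n:].to_numpy()
    return TwinPanelTable(out, schema, residualized=True)


def _ols_residuals(y: pd.Series, covs: list[pd.Series], name: str) -> pd.Series:
    ok = y.notna()
    for c in covs:
        ok &= c.notna()
    resid = pd.Series(np.nan, index=y.index)
    n_ok = int(ok.sum())
    if n_ok < 3:
        raise TwinDataError(
            f"variable {name}: only {n_ok} complete cases for residualisation")
    X = np.column_stack([np.ones(n_ok)]
                        + [c[ok].to_numpy(dtype=float) for c in covs])
    # drop constant covariate columns (e.g. sex in a single-sex file)
    keep = [0] + [k for k in range(1, X.shape[1]) if np.ptp(X[:, k]) > 0]
    X = X[:, keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise TwinDataError(
            f"variable {name}: rank-deficient covariate design "
            f"(collinear columns among intercept/age/sex)")
    yv = y[ok].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid[ok] = yv - X @ beta
    return resid


# ---------------------------------------------------------------------------
# difference scores and matrix conversion
# ---------------------------------------------------------------------------

def make_difference_scores(table: TwinPanelTable) -> DiffScoreTable:
    """Twin-difference scores per trait and occasion (twin 1 - twin 2).

    Antisymmetric under twin relabelling; missing whenever either twin's
    score is missing.
    """
    schema = table.schema
    data = {schema.pair_id: table.frame[schema.pair_id]}
    for occ in schema.occasions:
        for trait in schema.traits:
            d = (table.frame[schema.value_column(trait, occ, 1)]
                 - table.frame[schema.value_column(trait, occ, 2)])
            data[f"{trait}{occ}"] = d
    return DiffScoreTable(pd.DataFrame(data),
                          traits=schema.traits, occasions=schema.occasions)


def to_observed_matrix(table: TwinPanelTable | DiffScoreTable,
                       unit: str = "pair") -> ObservedMatrix:
    """Convert a (residualised) table to a model-ready matrix.

    ``unit='pair'`` gives one 18-column row per pair (twin 1's nine
    variables then twin 2's); ``'individual'`` stacks twins into 9-column
    rows with the pair id as cluster label; ``'difference'`` uses the
    twin-difference scores.
    """
    if isinstance(table, DiffScoreTable):
        if unit != "difference":
            raise ValueError("DiffScoreTable only supports unit='difference'")
        cols = trait_columns(table.traits, table.occasions)
        values = table.frame[cols].to_numpy(dtype=float)
        ids = table.frame.iloc[:, 0].to_numpy()
        return ObservedMatrix(values, cols, ids=ids, unit="difference")

    schema = table.schema
    stems = trait_columns(schema.traits, schema.occasions)
    if unit == "pair":
        cols = pair_manifest(schema.traits, schema.occasions)
        values = table.frame[
            [f"{s}_t1" for s in stems] + [f"{s}_t2" for s in stems]
        ].to_numpy(dtype=float)
        return ObservedMatrix(values, cols, ids=table.pair_ids, unit="pair")
    if unit == "individual":
        v1 = table.frame[[f"{s}_t1" for s in stems]].to_numpy(dtype=float)
        v2 = table.frame[[f"{s}_t2" for s in stems]].to_numpy(dtype=float)
        values = np.vstack([v1, v2])
        ids = np.concatenate([table.pair_ids, table.pair_ids])
        return ObservedMatrix(values, list(stems), ids=ids, unit="individual")
    if unit == "difference":
        return to_observed_matrix(make_difference_scores(table), "difference")
    raise ValueError(f"unknown unit tag: {unit!r}")
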