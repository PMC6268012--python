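"""Choice-panel container and long-format CSV readers/writers.

A stated-preference (SP) route-choice survey yields a *panel*: each respondent
``c`` faces ``K`` choice scenarios, each offering ``I`` alternatives described by
``M`` attributes.  The canonical interchange format is a long-format table with
one row per (respondent, scenario, alternative), a ``chosen`` flag, and one
column per attribute, plus a separate respondent-covariate table keyed by
respondent id.

Partitioned designs show only a subset of attributes in each scenario; unshown
attribute cells are left empty in the file and are recorded here in a boolean
availability mask.  Unavailable attributes contribute exactly zero to utility
and regret downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ChoicePanel", "PanelSchema", "read_choice_panel", "write_choice_panel"]


class PanelError(ValueError):
    """Raised for structurally invalid choice-panel inputs."""


@dataclass(frozen=True)
class PanelSchema:
    """Column-role mapping for the long-format alternatives file.

    Parameters
    ----------
    attribute_cols : tuple of str
        Numeric attribute columns taken as-is (e.g. exposure in ppb, travel
        time in minutes).
    categorical_cols : dict
        Maps a raw categorical column (holding level labels) to
        ``(levels, base_level)``.  Each categorical with L levels is expanded
        into L-1 dummy columns named ``"<col>_<level>"``, omitting the base.
    covariate_cols : tuple of str or None
        Covariate columns to read from the respondent table; ``None`` reads
        every non-id column.  An ``intercept`` column of ones is prepended if
        absent.
    """

    respondent_col: str = "respondent"
    scenario_col: str = "scenario"
    alternative_col: str = "alternative"
    chosen_col: str = "chosen"
    attribute_cols: tuple[str, ...] = ()
    categorical_cols: dict = field(default_factory=dict)
    covariate_cols: tuple[str, ...] | None = None

    def dummy_columns(self) -> dict[str, list[str]]:
        """Dummy column names per categorical, base level omitted."""
        out = {}
        for col, (levels, base) in self.categorical_cols.items():
            if base not in levels:
                raise PanelError(f"base level {base!r} not among levels of {col!r}")
            out[col] = [f"{col}_{lv}" for lv in levels if lv != base]
        return out

    def expanded_attribute_names(self) -> list[str]:
        names: list[str] = []
        for cols in self.dummy_columns().values():
            names.extend(cols)
        names.extend(self.attribute_cols)
        return names


@dataclass
class ChoicePanel:
    """Respondents x scenarios x alternatives attribute tensor with choices.

    Attributes
    ----------
    x : ndarray, shape (C, K, I, M)
        Attribute values; zero where unavailable.
    chosen : ndarray of int, shape (C, K), or None
        Index of the chosen alternative per scenario; ``None`` for a design
        skeleton whose choices have not been simulated yet.
    z : ndarray, shape (C, P)
        Respondent covariates including an intercept column.
    availability : ndarray of bool, shape (C, K, M)
        True where the attribute was shown in that scenario.
    dummy_groups : dict
        Optional map category -> list of dummy attribute names, used to check
        the one-hot invariant.
    true_segments : ndarray of int, shape (C,), or None
        Generating segment labels for simulated panels (diagnostics only;
        never read by estimation code).
    """

    x: np.ndarray
    chosen: np.ndarray | None
    z: np.ndarray
    attribute_names: list[str]
    covariate_names: list[str]
    availability: np.ndarray
    respondent_ids: np.ndarray | None = None
    dummy_groups: dict = field(default_factory=dict)
    true_segments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.availability = np.asarray(self.availability, dtype=bool)
        if self.chosen is not None:
            self.chosen = np.asarray(self.chosen, dtype=int)
        self.validate()

    # -- shape bookkeeping -------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return self.x.shape[0]

    @property
    def n_scenarios(self) -> int:
        return self.x.shape[1]

    @property
    def n_alternatives(self) -> int:
        return self.x.shape[2]

    @property
    def n_attributes(self) -> int:
        return self.x.shape[3]

    @property
    def n_obs(self) -> int:
        """Number of choice observations (C * K)."""
        return self.n_respondents * self.n_scenarios

    def attribute_index(self, names) -> np.ndarray:
        try:
            return np.array([self.attribute_names.index(n) for n in names], dtype=int)
        except ValueError as exc:
            raise PanelError(f"unknown attribute in {list(names)}: {exc}") from None

    def covariate_index(self, names) -> np.ndarray:
        try:
            return np.array([self.covariate_names.index(n) for n in names], dtype=int)
        except ValueError as exc:
            raise PanelError(f"unknown covariate in {list(names)}: {exc}") from None

    def validate(self) -> None:
        if self.x.ndim != 4:
            raise PanelError(f"x must be 4-d (C,K,I,M), got shape {self.x.shape}")
        C, K, I, M = self.x.shape
        if len(self.attribute_names) != M:
            raise PanelError("attribute_names length mismatch with x")
        if self.availability.shape != (C, K, M):
            raise PanelError("availability must have shape (C, K, M)")
        if self.z.shape[0] != C or self.z.shape[1] != len(self.covariate_names):
            raise PanelError("z shape mismatch with covariate_names")
        if self.chosen is not None:
            if self.chosen.shape != (C, K):
                raise PanelError("chosen must have shape (C, K)")
            if self.chosen.min(initial=0) < 0 or self.chosen.max(initial=0) >= I:
                raise PanelError("chosen index out of range [0, I)")
        av = self.availability[:, :, None, :]
        if not np.all(np.isfinite(np.where(av, self.x, 0.0))):
            raise PanelError("non-finite attribute value where availability is true")
        for cat, cols in self.dummy_groups.items():
            idx = self.attribute_index(cols)
            vals = self.x[..., idx]
            shown = np.broadcast_to(self.availability[:, :, None, idx], vals.shape)
            if not np.all(np.isin(vals[shown], (0.0, 1.0))):
                raise PanelError(f"dummy columns of {cat!r} must be 0/1")
            if np.any(vals.sum(axis=-1)[shown.any(axis=-1)] > 1 + 1e-12):
                raise PanelError(f"more than one level dummy set for {cat!r}")

    def with_choices(self, chosen: np.ndarray, true_segments=None) -> "ChoicePanel":
        return replace(self, chosen=np.asarray(chosen, dtype=int), true_segments=true_segments)


def read_choice_panel(alternatives_table, covariates_table, schema: PanelSchema) -> ChoicePanel:
    """Read a long-format alternatives CSV and a respondent-covariate CSV.

    Empty attribute cells mark the attribute unavailable in that scenario;
    availability must be consistent across the scenario's alternatives.
    """
    alts = pd.read_csv(alternatives_table, float_precision="round_trip")
    covs = pd.read_csv(covariates_table, float_precision="round_trip")

    rid, sid, aid = schema.respondent_col, schema.scenario_col, schema.alternative_col
    for col in (rid, sid, aid, schema.chosen_col):
        if col not in alts.columns:
            raise PanelError(f"alternatives table missing column {col!r}")
    if alts.duplicated([rid, sid, aid]).any():
        raise PanelError("duplicate (respondent, scenario, alternative) rows")

    # expand categorical level labels into base-omitted dummies
    dummy_groups: dict[str, list[str]] = {}
    for col, (levels, base) in schema.categorical_cols.items():
        if col not in alts.columns:
            raise PanelError(f"alternatives table missing categorical column {col!r}")
        bad = set(alts[col].dropna()) - set(levels)
        if bad:
            raise PanelError(f"unknown level(s) {sorted(bad)} in column {col!r}")
        cols = []
        for lv in levels:
            if lv == base:
                continue
            name = f"{col}_{lv}"
            alts[name] = np.where(alts[col].isna(), np.nan, (alts[col] == lv).astype(float))
            cols.append(name)
        dummy_groups[col] = cols

    attr_names = schema.expanded_attribute_names()
    for col in schema.attribute_cols:
        if col not in alts.columns:
            raise PanelError(f"alternatives table missing attribute column {col!r}")

    respondents = list(pd.unique(alts[rid]))
    missing = set(respondents) - set(covs[rid])
    if missing:
        raise PanelError(f"respondents absent from covariates table: {sorted(missing)[:5]}")

    scen_per_resp = alts.groupby(rid)[sid].nunique()
    alt_per_scen = alts.groupby([rid, sid])[aid].nunique()
    K = int(scen_per_resp.iloc[0])
    I = int(alt_per_scen.iloc[0])
    if not (scen_per_resp == K).all() or not (alt_per_scen == I).all():
        raise PanelError("panel must be rectangular: equal scenarios and alternatives throughout")
    C, M = len(respondents), len(attr_names)

    alts = alts.sort_values([rid, sid, aid], kind="stable")
    chosen_per_scen = alts.groupby([rid, sid])[schema.chosen_col].sum()
    if not (chosen_per_scen == 1).all():
        bad = chosen_per_scen[chosen_per_scen != 1].index[0]
        raise PanelError(f"scenario {bad} must have exactly one chosen alternative")

    raw = alts[attr_names].to_numpy(dtype=float).reshape(C, K, I, M)
    chosen_flag = alts[schema.chosen_col].to_numpy().reshape(C, K, I)
    chosen = chosen_flag.argmax(axis=2)

    nan = np.isnan(raw)
    shown = ~nan
    if np.any(shown.any(axis=2) & nan.any(axis=2)):
        raise PanelError("attribute availability inconsistent across a scenario's alternatives")
    availability = shown.all(axis=2)
    x = np.where(nan, 0.0, raw)

    covs = covs.set_index(rid).loc[respondents].reset_index()
    cov_cols = list(schema.covariate_cols) if schema.covariate_cols is not None else [
        c for c in covs.columns if c != rid
    ]
    for col in cov_cols:
        if col not in covs.columns:
            raise PanelError(f"covariates table missing column {col!r}")
    if "intercept" not in cov_cols:
        covs["intercept"] = 1.0
        cov_cols = ["intercept"] + cov_cols
    z = covs[cov_cols].to_numpy(dtype=float)

    return ChoicePanel(
        x=x,
        chosen=chosen,
        z=z,
        attribute_names=attr_names,
        covariate_names=cov_cols,
        availability=availability,
        respondent_ids=np.asarray(respondents),
        dummy_groups=dummy_groups,
    )


def write_choice_panel(panel: ChoicePanel, alternatives_path, covariates_path,
                       schema: PanelSchema | None = None) -> None:
    """Write the CSV pair ``read_choice_panel`` consumes (round-trip exact).

    Attributes are written under their expanded (dummy-coded) names; a
    matching schema for re-reading lists them all as ``attribute_cols``.
    """
    C, K, I, M = panel.x.shape
    rid = panel.respondent_ids if panel.respondent_ids is not None else np.arange(C)
    rows = {
        "respondent": np.repeat(rid, K * I),
        "scenario": np.tile(np.repeat(np.arange(K), I), C),
        "alternative": np.tile(np.arange(I), C * K),
    }
    flat = panel.x.reshape(C * K * I, M).astype(object)
    avail = np.repeat(panel.availability.reshape(C * K, M), I, axis=0)
    flat[~avail] = np.nan
    chosen = np.zeros((C, K, I), dtype=int)
    if panel.chosen is not None:
        np.put_along_axis(chosen, panel.chosen[:, :, None], 1, axis=2)
    rows["chosen"] = chosen.reshape(-1)
    df = pd.DataFrame(rows)
    for j, name in enumerate(panel.attribute_names):
        df[name] = flat[:, j]
    df.to_csv(alternatives_path, index=False)

    cov = pd.DataFrame({"respondent": rid})
    for j, name in enumerate(panel.covariate_names):
        cov[name] = panel.z[:, j]
    cov.to_csv(covariates_path, index=False)


def roundtrip_schema(panel: ChoicePanel) -> PanelSchema:
    """Schema that re-reads the files ``write_choice_panel`` produced."""
    return PanelSchema(
        attribute_cols=tuple(panel.attribute_names),
        covariate_cols=tuple(panel.covariate_names),
    )
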