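"""Long-format tables and random-intercept linear mixed-effects models.

The inference layer follows the statsmodels idiom: a
:class:`MixedEffectsModel` is built from a tidy DataFrame (usually via
:meth:`~MixedEffectsModel.from_spec` with one of the predefined study
models), and :meth:`~MixedEffectsModel.fit` returns a
:class:`MixedEffectsResults` carrying fixed-effect estimates, Wald z tests,
variance components and Benjamini–Hochberg-corrected post-hoc contrasts.

Five model families are predefined: the frontal entropy models (all
subjects, and users-only with age of first use), the matching spectral
power models, the regional entropy and power models collapsing over groups,
and the exploratory frontal-parietal cross-entropy model.  All use random
intercepts for subjects; fixed-effect significance is assessed by Wald z
against the standard normal (no small-sample df correction), and FDR
correction is applied within named post-hoc contrast families only —
omnibus terms and planned covariates stay uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .entropy import BIN_ORDER, MSEProfile, XMSEProfile

__all__ = [
    "bh_fdr",
    "build_long_table",
    "ModelSpec",
    "MODEL_SPECS",
    "MixedEffectsModel",
    "MixedEffectsResults",
    "fit_lme",
]


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of p-values.

    ``q_i = min_{j: p_j ≥ p_i} p_j · n / rank_j``, clipped to 1; the map is
    monotone, so the ordering of p-values is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Long-table construction
# ---------------------------------------------------------------------------

def _merge_metadata(df: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    missing = set(df["subject_id"]) - set(metadata["subject_id"])
    if missing:
        raise ValueError(f"subjects missing from metadata: {sorted(missing)}")
    return df.merge(metadata, on="subject_id", how="left")


def build_long_table(
    profiles: Iterable[MSEProfile] | Iterable[XMSEProfile] | pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "binned",
) -> pd.DataFrame:
    """Assemble the LME design table from entropy profiles or band powers.

    Parameters
    ----------
    profiles
        A list of :class:`MSEProfile` (column ``entropy``), a list of
        :class:`XMSEProfile` (column ``xmse``), or the tidy band-power
        frame from :func:`~neuroentropy.spectral.band_power_table`.
    metadata
        Per-subject table with subject_id, group, SPQTotal, AgeFirstUse.
    mode : {"binned", "per-scale"}
        Binned mode (default) averages the five scales of each bin into a
        single response per subject × lobe × bin; per-scale mode keeps one
        row per scale, labelled with its bin.  Undefined (NaN) entropy
        values are excluded from bin means and dropped from per-scale rows.

    Returns
    -------
    DataFrame
        One row per analysis cell with a ``bin_index`` numeric coding
        (fine=0 … very-coarse=3) alongside the categorical ``scale_bin``.
    """
    if isinstance(profiles, pd.DataFrame):
        return _merge_metadata(profiles.copy(), metadata)

    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    if mode not in ("binned", "per-scale"):
        raise ValueError("mode must be 'binned' or 'per-scale'")

    rows = []
    for prof in profiles:
        if isinstance(prof, MSEProfile):
            values, value_col = prof.entropy_by_scale, "entropy"
            unit = {"lobe": prof.lobe}
        elif isinstance(prof, XMSEProfile):
            values, value_col = prof.cross_entropy_by_scale, "xmse"
            unit = {"lobe_pair": "-".join(prof.lobe_pair)}
        else:
            raise TypeError(f"unsupported profile type {type(prof).__name__}")
        if mode == "binned":
            for b, label in enumerate(BIN_ORDER):
                scales = [s for s in range(5 * b + 1, 5 * b + 6) if s <= len(values)]
                if not scales:
                    continue
                vals = values[np.array(scales) - 1]
                if not np.any(np.isfinite(vals)):
                    continue  # all-undefined cell dropped (logged by caller)
                rows.append(
                    {"subject_id": prof.subject_id, **unit, "scale_bin": label,
                     "bin_index": b, value_col: float(np.nanmean(vals))}
                )
        else:
            for s, v in enumerate(values, start=1):
                if not np.isfinite(v):
                    continue
                label = BIN_ORDER[(s - 1) // 5]
                rows.append(
                    {"subject_id": prof.subject_id, **unit, "scale_bin": label,
                     "bin_index": (s - 1) // 5, "scale": s, value_col: float(v)}
                )
    return _merge_metadata(pd.DataFrame(rows), metadata)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one study model.

    ``formula`` is a patsy formula with treatment-coded factors and explicit
    reference levels; ``subset`` optionally restricts the table (the
    users-only models); ``posthoc_families`` maps a family name to the
    substrings that select its fixed-effect terms for FDR correction (a
    term is in the family when it contains every listed substring; a
    substring prefixed with ``!`` must be absent).
    """

    name: str
    response: str
    formula: str
    subset: str | None = None
    posthoc_families: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def apply_subset(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.subset == "users":
            return table[table["group"] != "non-user"].copy()
        return table


_G_NON = "C(group, Treatment('non-user'))"
_G_FREQ = "C(group, Treatment('frequent'))"
_BIN_FINE = "C(scale_bin, Treatment('fine'))"
_BIN_COARSE = "C(scale_bin, Treatment('coarse'))"
_BAND_ALPHA = "C(band, Treatment('alpha'))"
_LOBE_FRONT = "C(lobe, Treatment('frontal'))"

MODEL_SPECS: dict[str, ModelSpec] = {
    # Frontal entropy, all subjects; group reference = non-users, bin
    # reference = fine, so the interaction terms are the attenuation of each
    # user group's entropy rise relative to non-users.
    "1A": ModelSpec(
        "1A", "entropy",
        f"entropy ~ {_G_NON} * {_BIN_FINE} + SPQTotal * {_BIN_FINE}",
        posthoc_families={
            "group_x_bin": (f"{_G_NON}[T.", ":C(scale_bin"),
            "spq_x_bin": ("SPQTotal:",),
        },
    ),
    # Frontal entropy, users only, with age of first use as a covariate.
    "1B": ModelSpec(
        "1B", "entropy",
        f"entropy ~ C(group, Treatment('low-frequency')) * {_BIN_FINE}"
        f" + AgeFirstUse + SPQTotal * {_BIN_FINE}",
        subset="users",
        posthoc_families={
            "group_x_bin": ("C(group, Treatment('low-frequency'))[T.", ":C(scale_bin"),
        },
    ),
    # Frontal spectral power; group reference = frequent users, band
    # reference = alpha, matching the reported contrasts.
    "2A": ModelSpec(
        "2A", "log_power",
        f"log_power ~ {_G_FREQ} * {_BAND_ALPHA} + SPQTotal * {_BAND_ALPHA}",
        posthoc_families={"group_x_band": (f"{_G_FREQ}[T.", ":C(band")},
    ),
    "2B": ModelSpec(
        "2B", "log_power",
        f"log_power ~ C(group, Treatment('low-frequency')) * {_BAND_ALPHA}"
        f" + AgeFirstUse + SPQTotal * {_BAND_ALPHA}",
        subset="users",
        posthoc_families={
            "group_x_band": ("C(group, Treatment('low-frequency'))[T.", ":C(band"),
        },
    ),
    # Regional models collapse across groups.
    "regional-mse": ModelSpec(
        "regional-mse", "entropy",
        f"entropy ~ {_LOBE_FRONT} * {_BIN_FINE}",
        posthoc_families={
            "lobe": (f"{_LOBE_FRONT}[T.", "!:"),
            "lobe_x_bin": ("C(lobe", ":C(scale_bin"),
        },
    ),
    "regional-fft": ModelSpec(
        "regional-fft", "log_power",
        f"log_power ~ {_LOBE_FRONT} * {_BAND_ALPHA}",
        posthoc_families={"lobe_x_band": ("C(lobe", ":C(band")},
    ),
    # Frontal-parietal cross-entropy; SPQ enters as a main effect only,
    # scale-bin reference = coarse.
    "xmse": ModelSpec(
        "xmse", "xmse",
        f"xmse ~ {_G_FREQ} * {_BIN_COARSE} + SPQTotal",
        posthoc_families={"group_x_bin": (f"{_G_FREQ}[T.", ":C(scale_bin")},
    ),
}


def _match_family(term: str, patterns: tuple[str, ...] | str) -> bool:
    if isinstance(patterns, str):
        patterns = (patterns,)
    for pat in patterns:
        if pat.startswith("!"):
            if pat[1:] in term:
                return False
        elif pat not in term:
            return False
    return True


# ---------------------------------------------------------------------------
# Model and results objects
# ---------------------------------------------------------------------------

class MixedEffectsModel:
    """Random-intercept linear mixed model for one study design.

    Thin statsmodels ``MixedLM`` wrapper: build from a formula and a tidy
    table, fit by REML, and read fixed effects with Wald z tests off the
    returned :class:`MixedEffectsResults`.

    Examples
    --------
    >>> model = MixedEffectsModel.from_spec(MODEL_SPECS["1A"], table)
    >>> res = model.fit()
    >>> res.fixed_effects          # doctest: +SKIP
    """

    def __init__(self, formula: str, data: pd.DataFrame, groups: str = "subject_id",
                 spec: ModelSpec | None = None) -> None:
        data = data.dropna(subset=_formula_columns(formula, data)).copy()
        counts = data.groupby(groups).size()
        if (counts < 2).any():
            raise ValueError(
                f"subjects with < 2 observations: {list(counts[counts < 2].index)}"
            )
        self.formula = formula
        self.data = data
        self.groups = groups
        self.spec = spec
        self._model = smf.mixedlm(formula, data, groups=data[groups])
        self._check_rank()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     groups: str = "subject_id") -> "MixedEffectsModel":
        return cls(formula, data, groups)

    @classmethod
    def from_spec(cls, spec: ModelSpec | str, table: pd.DataFrame,
                  groups: str = "subject_id") -> "MixedEffectsModel":
        if isinstance(spec, str):
            spec = MODEL_SPECS[spec]
        return cls(spec.formula, spec.apply_subset(table), groups, spec=spec)

    def _check_rank(self) -> None:
        X = self._model.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns for the caller
            names = list(self._model.exog_names)
            bad = []
            keep: list[int] = []
            for i in range(X.shape[1]):
                if np.linalg.matrix_rank(X[:, keep + [i]]) == len(keep):
                    bad.append(names[i])
                else:
                    keep.append(i)
            raise ValueError(f"singular design; collinear terms: {bad}")

    def fit(self, reml: bool = True, **kwargs) -> "MixedEffectsResults":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = self._model.fit(reml=reml, **kwargs)
        if not res.converged:
            raise RuntimeError(
                f"mixed model did not converge (formula: {self.formula}); "
                "try rescaling the response or simplifying the design"
            )
        return MixedEffectsResults(self, res)


class MixedEffectsResults:
    """Fitted fixed effects, variance components and post-hoc machinery."""

    def __init__(self, model: MixedEffectsModel, sm_result) -> None:
        self.model = model
        self._res = sm_result

    @property
    def converged(self) -> bool:
        return bool(self._res.converged)

    @property
    def fixed_effects(self) -> pd.DataFrame:
        """Term, estimate β, SE, Wald z and two-sided normal p."""
        fe = self._res.fe_params
        se = self._res.bse_fe
        z = fe / se
        p = 2 * sps.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": fe.index, "estimate": fe.values, "se": se.values,
             "z": z.values, "p": p}
        ).set_index("term")

    @property
    def random_intercept_var(self) -> float:
        return float(np.asarray(self._res.cov_re)[0, 0])

    @property
    def residual_var(self) -> float:
        return float(self._res.scale)

    @property
    def icc(self) -> float:
        """Intraclass correlation implied by the variance components."""
        v = self.random_intercept_var
        return v / (v + self.residual_var)

    def wald_p(self, term: str) -> float:
        """Two-sided Wald p-value of one fixed-effect coefficient."""
        row = self.fixed_effects.loc[term]
        return float(row["p"])

    def wald_joint(self, terms: Sequence[str]) -> float:
        """Joint Wald chi-square test that the named coefficients are all 0."""
        names = list(self._res.fe_params.index)
        L = np.zeros((len(terms), len(self._res.params)))
        for r, t in enumerate(terms):
            L[r, names.index(t)] = 1.0
        wt = self._res.wald_test(L, scalar=True)
        return float(wt.pvalue)

    def posthoc_contrasts(self, family: Sequence[str] | str) -> pd.DataFrame:
        """BH-FDR within one named contrast family.

        ``family`` is either a list of term labels or the name of a family
        defined in the model's :class:`ModelSpec` (matched by substring).
        Returns the fixed-effect rows with an added ``q`` column; q ≥ p
        always.
        """
        fe = self.fixed_effects
        if isinstance(family, str):
            if self.model.spec is None or family not in self.model.spec.posthoc_families:
                raise KeyError(f"unknown post-hoc family {family!r}")
            pat = self.model.spec.posthoc_families[family]
            terms = [t for t in fe.index if _match_family(t, pat)]
        else:
            terms = list(family)
        if not terms:
            raise ValueError("post-hoc family selected no terms")
        sub = fe.loc[terms].copy()
        sub["q"] = bh_fdr(sub["p"].to_numpy())
        return sub

    def summary(self):
        """statsmodels summary table of the underlying fit."""
        return self._res.summary()

    def tidy(self) -> pd.DataFrame:
        """Fixed effects as a tidy frame with q-values filled in for every
        term covered by a post-hoc family (NaN elsewhere)."""
        fe = self.fixed_effects.copy()
        fe["q"] = np.nan
        fe["family"] = ""
        if self.model.spec is not None:
            for fam in self.model.spec.posthoc_families:
                sub = self.posthoc_contrasts(fam)
                fe.loc[sub.index, "q"] = sub["q"]
                fe.loc[sub.index, "family"] = fam
        return fe.reset_index()


def fit_lme(table: pd.DataFrame, spec: ModelSpec | str) -> MixedEffectsResults:
    """Fit one of the predefined study models to a long table."""
    return MixedEffectsModel.from_spec(spec, table).fit()


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c in formula]
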