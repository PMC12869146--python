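"""Relative risks, DIC model comparison and exceedance-probability maps.

Turns retained MCMC draws into the reported quantities of a BYM disease-
mapping analysis:

* relative risks per covariate — exp of the posterior mean coefficient,
  with 95% credible intervals as exp of the 2.5%/97.5% coefficient
  quantiles (identical to quantiles of the exponentiated draws, since
  quantiles commute with monotone maps);
* the deviance information criterion DIC = Dbar + pD with pD = Dbar -
  D(posterior mean), using the conditional focus (deviance evaluated given
  the random effects);
* per-area exceedance probabilities — the posterior probability that an
  area's fitted rate falls below a stated fraction of a reference rate (by
  default the population-weighted state-average fitted rate, computed
  within each draw so reference and rates stay coherent).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bym_model import (
    AdjacencyMatrix,
    AreaYearPanel,
    McmcConfig,
    ModelSpec,
    PosteriorSamples,
    Priors,
    fit_bym_poisson,
    log_likelihood,
)

MIN_DRAWS = 100


def summarize_rr(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Relative risks with credible intervals, one row per covariate.

    RR = exp(posterior mean of beta_j); interval = exp of the coefficient's
    sample quantiles.  All RRs are per 1 SD of the (standardized) covariate.
    """
    if samples.n_draws < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} retained draws, got {samples.n_draws}"
        )
    alpha = (1.0 - level) / 2.0
    rows = []
    for k, nm in enumerate(samples.covariate_names):
        draws = samples.beta[:, k]
        rows.append({
            "covariate": nm,
            "rr": float(np.exp(draws.mean())),
            "rr_lower": float(np.exp(np.quantile(draws, alpha))),
            "rr_upper": float(np.exp(np.quantile(draws, 1 - alpha))),
        })
    return pd.DataFrame(rows, columns=["covariate", "rr", "rr_lower", "rr_upper"])


@dataclass(frozen=True)
class DicResult:
    dbar: float      # posterior mean deviance
    d_hat: float     # deviance at the posterior means
    p_d: float       # effective number of parameters, dbar - d_hat
    dic: float       # dbar + p_d

    def __post_init__(self) -> None:
        if abs(self.dic - (self.dbar + self.p_d)) > 1e-9 * max(1.0, abs(self.dic)):
            raise ValueError("DIC identity dic = dbar + p_d violated")


def compute_dic(samples: PosteriorSamples, panel: AreaYearPanel) -> DicResult:
    """DIC with the conditional focus: D(theta) given the random effects.

    Dbar averages the stored per-draw deviances; D-hat plugs in the
    posterior means of beta0, beta, u and v.  Negative pD (possible under
    poor mixing or strong non-normality) triggers a warning, not a failure.
    """
    if samples.log_likelihood is None or len(samples.log_likelihood) == 0:
        raise ValueError("samples carry no per-draw log-likelihood trace")
    dbar = float(np.mean(-2.0 * samples.log_likelihood))
    X = panel.subset_covariates(samples.covariate_names)
    d_hat = -2.0 * log_likelihood(
        panel,
        float(samples.beta0.mean()),
        samples.beta.mean(axis=0),
        samples.u.mean(axis=0),
        samples.v.mean(axis=0),
        X=X,
    )
    p_d = dbar - d_hat
    if p_d < 0:
        warnings.warn(f"negative effective parameter count pD={p_d:.3f}",
                      UserWarning, stacklevel=2)
    return DicResult(dbar=dbar, d_hat=d_hat, p_d=p_d, dic=dbar + p_d)


def compare_models(
    panel: AreaYearPanel,
    adjacency: AdjacencyMatrix,
    priors: Priors,
    mcmc: McmcConfig,
    specs: Sequence[ModelSpec],
) -> pd.DataFrame:
    """Fit every candidate model and rank by DIC (lower is better).

    Each spec is fitted with a spec-indexed seed (base seed + index) so runs
    are reproducible yet independent.  Returns a frame sorted by DIC with
    the winner flagged; a failing fit raises an error naming its spec.
    """
    if len(specs) < 2:
        raise ValueError("model comparison needs at least 2 specs")
    rows = []
    for k, spec in enumerate(specs):
        cfg = replace(mcmc, seed=mcmc.seed + k)
        try:
            samples = fit_bym_poisson(panel, adjacency, spec, priors, cfg)
            dic = compute_dic(samples, panel)
        except Exception as exc:  # noqa: BLE001 — context added, then re-raised
            raise RuntimeError(f"model {spec.name!r} failed to fit: {exc}") from exc
        rows.append({
            "model": spec.name, "dbar": dic.dbar, "d_hat": dic.d_hat,
            "p_d": dic.p_d, "dic": dic.dic,
        })
    table = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    table["best"] = [i == 0 for i in range(len(table))]
    return table


def fitted_rate_draws(samples: PosteriorSamples, panel: AreaYearPanel) -> np.ndarray:
    """Per-draw fitted per-person rates exp(eta_i), shape (n_draws, n_areas)."""
    X = panel.subset_covariates(samples.covariate_names)
    eta = (
        samples.beta0[:, None]
        + (samples.beta @ X.T if X.shape[1] else 0.0)
        + samples.u
        + samples.v
    )
    return np.exp(eta)


def exceedance_probabilities(
    samples: PosteriorSamples,
    panel: AreaYearPanel,
    threshold_fraction: float,
    reference: str = "state_mean",
    fixed_value: float | None = None,
) -> pd.DataFrame:
    """Posterior probability each area's fitted rate is below a threshold.

    For each retained draw the fitted rate exp(eta_i) is compared with
    ``threshold_fraction`` times a reference rate; the probability is the
    fraction of draws below.  ``reference='state_mean'`` uses the
    population-weighted mean fitted rate of that same draw (so a "50% below
    the state average" map uses threshold_fraction=0.5);
    ``reference='fixed_value'`` compares against ``fixed_value`` directly.
    """
    if threshold_fraction <= 0:
        raise ValueError("threshold_fraction must be positive")
    rates = fitted_rate_draws(samples, panel)
    if reference == "state_mean":
        w = panel.offset / panel.offset.sum()
        ref = rates @ w  # one reference per draw
    elif reference == "fixed_value":
        if fixed_value is None or fixed_value <= 0:
            raise ValueError("fixed_value reference requires a positive fixed_value")
        ref = np.full(rates.shape[0], float(fixed_value))
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    below = rates < threshold_fraction * ref[:, None]
    return pd.DataFrame({
        "area_id": panel.area_ids,
        "probability": below.mean(axis=0),
        "threshold_fraction": threshold_fraction,
        "reference": reference,
    })


def attach_exceedance_to_geojson(
    geojson_path: str | Path,
    exceedance: pd.DataFrame,
    out_path: str | Path,
    property_name: str = "exceedance_probability",
) -> None:
    """Join exceedance probabilities onto GeoJSON features (for choropleths)."""
    with open(geojson_path) as fh:
        doc = json.load(fh)
    probs = dict(zip(exceedance["area_id"], exceedance["probability"]))
    for feat in doc.get("features", []):
        aid = str((feat.get("properties") or {}).get("area_id"))
        if aid in probs:
            feat.setdefault("properties", {})[property_name] = float(probs[aid])
    with open(out_path, "w") as fh:
        json.dump(doc, fh)


def rr_table_csv(crude: pd.DataFrame, adjusted: pd.DataFrame, path: str | Path) -> None:
    """Side-by-side crude/adjusted RR table in the style of a results table."""
    merged = crude.merge(adjusted, on="covariate", suffixes=("_crude", "_adjusted"),
                         how="outer")
    merged.to_csv(path, index=False)
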