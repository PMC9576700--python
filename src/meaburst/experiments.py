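"""In-silico experiments: fit scans, drop-out swaps, connectivity scans.

Three experiment families probe how single-neuron properties shape the
network burst frequency:

* ``run_fit_scan`` — a 2-D scan over membrane capacitance C_m and passive
  time constant tau_m (realized as g_L = C_m / tau_m), analyzed with the
  same spectral pipeline as recorded data; ``select_top_fit`` picks the
  combination whose simulated peak lies closest to a measured target.
* ``run_dropout_experiment`` — swaps a named parameter subset between two
  genotype parameter sets (adaptation = (a, b, tau_w), the model's
  representation of intrinsic Na+/K+ currents; membrane = (C_m, E_L))
  to attribute the network-level frequency change to that subset.
* ``run_connectivity_scan`` — a grid over subthreshold adaptation a and
  connection probability p, summarizing how burst frequency moves with
  network connectivity versus intrinsic adaptation.

Every scan row carries a status in {ok, excluded, failed}; no
combination goes silently missing, and failed simulations do not abort
the remaining rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, NoFitError
from .network import (
    NetworkConfig,
    NeuronParameters,
    SpikeRaster,
    group_into_electrodes,
    simulate,
)
from .spectral import (
    BurstFrequencyResult,
    WelchSettings,
    peak_burst_frequency,
    population_average_spectrum,
)
from .synth import GenotypeParameterSet

__all__ = [
    "AnalysisSettings",
    "ScanResult",
    "culture_config",
    "scaled_config",
    "simulate_and_analyze",
    "run_fit_scan",
    "select_top_fit",
    "dropout_swap",
    "run_dropout_experiment",
    "run_connectivity_scan",
    "connectivity_trend",
    "DROPOUT_SUBSETS",
]

# Parameter subsets exchanged by dropout_swap. "adaptation" carries the
# model's stand-in for intrinsic Na+/K+ currents (tau_w shapes those
# currents and travels with them); "membrane" carries capacitance and
# resting potential. Override by passing an explicit field tuple.
DROPOUT_SUBSETS: dict[str, tuple[str, ...]] = {
    "adaptation": ("a", "b", "tau_w"),
    "membrane": ("C_m", "E_L"),
}

#: External synaptic weight (nS per event) of the standard culture-like
#: operating point: the summed external conductance keeps neurons a few
#: millivolts below threshold, so isolated neurons are nearly silent and
#: rhythm requires recurrent excitation. The genotype fixtures are
#: calibrated against this drive; see docs/methods.md.
DEFAULT_W_EXT = 0.14


def culture_config(seed: int = 0, **overrides) -> NetworkConfig:
    """Full-scale run profile: 1000 neurons, 300 s, 0.1 ms step."""
    kw = dict(
        n_neurons=1000,
        connection_probability=0.05,
        duration=300.0,
        dt=0.1,
        w_ext=DEFAULT_W_EXT,
        v_init_jitter=2.0,
        seed=seed,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


def scaled_config(seed: int = 0, **overrides) -> NetworkConfig:
    """Reduced test profile: 200 neurons, 60 s (size-compensated
    recurrent weights keep the dynamics in the full-scale regime)."""
    kw = dict(n_neurons=200, duration=60.0)
    kw.update(overrides)
    return culture_config(seed, **kw)


@dataclass(frozen=True)
class AnalysisSettings:
    """Spectral-analysis knobs applied to simulated rasters.

    Simulated populations are merged into ``n_electrodes`` multiunit
    channels before spectral analysis, mirroring how the cultures are
    observed through a 64-channel MEA.
    """

    n_electrodes: int = 64
    n_surrogates: int = 3
    welch: WelchSettings | None = None
    band: tuple = (0.0, 1.0)


def simulate_and_analyze(
    params: NeuronParameters,
    config: NetworkConfig,
    analysis: AnalysisSettings = AnalysisSettings(),
    return_raster: bool = False,
):
    """Simulate one network and extract its population peak burst frequency.

    Chain: simulate -> merge neurons into electrode channels -> per-channel
    1 kHz binning, Welch PSD, permuted-surrogate dB ratio -> population
    average -> global-peak extraction in (0, 1] Hz.
    """
    raster = simulate(config, params)
    if raster.total_spikes == 0:
        result = BurstFrequencyResult(
            source_id="population-average",
            frequency=None,
            peak_db=None,
            excluded=True,
            reason="no-spikes",
            band=analysis.band,
        )
        return (result, raster) if return_raster else result
    grouped = group_into_electrodes(
        raster, min(analysis.n_electrodes, raster.n_sources), seed=config.seed
    )
    spectrum = population_average_spectrum(
        grouped,
        settings=analysis.welch,
        n_surrogates=analysis.n_surrogates,
        seed=config.seed,
    )
    result = peak_burst_frequency(spectrum, band=analysis.band)
    return (result, raster) if return_raster else result


@dataclass(frozen=True)
class ScanResult:
    """Tidy table of scan rows plus the settings that produced them.

    ``table`` columns: the scanned parameter names, ``seed``,
    ``peak_hz`` (NaN when excluded/failed), ``status`` in
    {ok, excluded, failed}, ``detail`` (exclusion reason or error).
    """

    table: pd.DataFrame
    param_names: tuple
    config: NetworkConfig
    analysis: AnalysisSettings

    def summary(self) -> pd.DataFrame:
        """Median peak and dispersion per parameter combination."""
        g = self.table.groupby(list(self.param_names), dropna=False)
        out = g.agg(
            median_peak_hz=("peak_hz", "median"),
            peak_range_hz=("peak_hz", lambda x: np.nan if x.isna().all() else x.max() - x.min()),
            n_ok=("status", lambda s: int((s == "ok").sum())),
            n_rows=("status", "size"),
        )
        return out.reset_index()


def _scan(
    combos: list[dict],
    param_names: tuple,
    base_params: NeuronParameters,
    config: NetworkConfig,
    seeds,
    analysis: AnalysisSettings,
    config_overrides=None,
) -> ScanResult:
    rows = []
    for combo in combos:
        for seed in seeds:
            row = dict(combo)
            row["seed"] = seed
            try:
                valid = {f.name for f in base_params.__dataclass_fields__.values()}
                params = replace(
                    base_params,
                    **{k: v for k, v in combo.items() if k in valid},
                )
                cfg = replace(config, seed=seed)
                if config_overrides:
                    cfg = replace(cfg, **config_overrides(combo))
                res = simulate_and_analyze(params, cfg, analysis)
                if res.excluded:
                    row.update(peak_hz=np.nan, status="excluded", detail=res.reason or "")
                else:
                    row.update(peak_hz=res.frequency, status="ok", detail="")
            except Exception as exc:  # keep scanning; record the failure
                row.update(peak_hz=np.nan, status="failed", detail=f"{type(exc).__name__}: {exc}")
            rows.append(row)
    table = pd.DataFrame(rows)
    return ScanResult(table=table, param_names=param_names, config=config, analysis=analysis)


def run_fit_scan(
    cm_values,
    tau_m_values,
    base_params: NeuronParameters,
    config: NetworkConfig,
    seeds=(0, 1, 2),
    analysis: AnalysisSettings = AnalysisSettings(),
) -> ScanResult:
    """2-D scan over (C_m, tau_m); tau_m is realized by g_L = C_m / tau_m."""
    cm_values = list(cm_values)
    tau_m_values = list(tau_m_values)
    if not cm_values or not tau_m_values:
        raise InvalidConfigError("fit-scan grid must be nonempty")
    combos = [
        {"C_m": float(cm), "tau_m": float(tm), "g_L": float(cm) / float(tm)}
        for cm, tm in product(cm_values, tau_m_values)
    ]
    return _scan(combos, ("C_m", "tau_m"), base_params, config, seeds, analysis)


def select_top_fit(scan: ScanResult, target_peak: float):
    """Row combination with median peak closest to ``target_peak`` (Hz).

    Ties break toward the smaller across-seed dispersion, then by
    lexicographic parameter order; the returned record carries a
    ``tie`` flag when a tie-break was applied.
    """
    summ = scan.summary()
    ok = summ[summ["n_ok"] > 0].copy()
    if ok.empty:
        raise NoFitError("every scanned combination was excluded or failed")
    ok["abs_diff"] = (ok["median_peak_hz"] - target_peak).abs()
    best = ok["abs_diff"].min()
    cands = ok[np.isclose(ok["abs_diff"], best)].copy()
    tie = len(cands) > 1
    cands = cands.sort_values(
        ["peak_range_hz"] + list(scan.param_names), na_position="last"
    )
    rec = cands.iloc[0].to_dict()
    rec["tie"] = tie
    return rec


def dropout_swap(
    base: GenotypeParameterSet,
    donor: GenotypeParameterSet,
    subset: str | tuple,
) -> GenotypeParameterSet:
    """Replace one parameter subset of ``base`` with ``donor``'s values.

    ``subset`` is "adaptation", "membrane", or an explicit tuple of
    NeuronParameters field names. All other fields stay with ``base``.
    """
    if isinstance(subset, str):
        try:
            fields = DROPOUT_SUBSETS[subset]
        except KeyError:
            raise InvalidConfigError(
                f"unknown drop-out subset {subset!r}; known: {sorted(DROPOUT_SUBSETS)}"
            ) from None
        tag = subset
    else:
        fields = tuple(subset)
        tag = "+".join(fields)
    overrides = {f: getattr(donor.params, f) for f in fields}
    return GenotypeParameterSet(
        label=f"{base.label}+{donor.label}-{tag}",
        params=replace(base.params, **overrides),
        provenance={
            "base": base.label,
            "donor": donor.label,
            "swapped": ", ".join(fields),
        },
    )


def run_dropout_experiment(
    wt: GenotypeParameterSet,
    null: GenotypeParameterSet,
    config: NetworkConfig,
    seeds=(0, 1, 2),
    analysis: AnalysisSettings = AnalysisSettings(),
    keep_rasters: bool = False,
):
    """Simulate the six drop-out conditions over replicate seeds.

    Conditions: WT, NULL, NULL with WT adaptation, NULL with WT membrane,
    WT with NULL adaptation, WT with NULL membrane. Returns a tidy
    DataFrame (condition, seed, peak_hz, status, detail) and, optionally,
    a dict of example rasters (first seed of each condition).
    """
    conditions = {
        wt.label: wt,
        null.label: null,
        f"{null.label}+{wt.label}-adaptation": dropout_swap(null, wt, "adaptation"),
        f"{null.label}+{wt.label}-membrane": dropout_swap(null, wt, "membrane"),
        f"{wt.label}+{null.label}-adaptation": dropout_swap(wt, null, "adaptation"),
        f"{wt.label}+{null.label}-membrane": dropout_swap(wt, null, "membrane"),
    }
    rows = []
    rasters: dict[str, SpikeRaster] = {}
    for name, gset in conditions.items():
        for seed in seeds:
            row = {"condition": name, "seed": seed}
            try:
                res, raster = simulate_and_analyze(
                    gset.params, replace(config, seed=seed), analysis, return_raster=True
                )
                if keep_rasters and seed == seeds[0]:
                    rasters[name] = raster
                if res.excluded:
                    row.update(peak_hz=np.nan, status="excluded", detail=res.reason or "")
                else:
                    row.update(peak_hz=res.frequency, status="ok", detail="")
            except Exception as exc:
                row.update(peak_hz=np.nan, status="failed", detail=f"{type(exc).__name__}: {exc}")
            rows.append(row)
    table = pd.DataFrame(rows)
    return (table, rasters) if keep_rasters else table


def run_connectivity_scan(
    a_values,
    p_values,
    base_params: NeuronParameters,
    config: NetworkConfig,
    seeds=(0, 1, 2),
    analysis: AnalysisSettings = AnalysisSettings(),
) -> ScanResult:
    """Grid over subthreshold adaptation a (nS) and connection
    probability p, with a monotonicity summary of peak frequency vs p."""
    a_values = list(a_values)
    p_values = list(p_values)
    if not a_values or not p_values:
        raise InvalidConfigError("connectivity-scan grid must be nonempty")
    combos = [
        {"a": float(a), "connection_probability": float(p)}
        for a, p in product(a_values, p_values)
    ]
    return _scan(
        combos,
        ("a", "connection_probability"),
        base_params,
        config,
        seeds,
        analysis,
        config_overrides=lambda c: {
            "connection_probability": c["connection_probability"]
        },
    )


def connectivity_trend(scan: ScanResult) -> pd.DataFrame:
    """Per-a sign of the association between p and median peak frequency.

    Returns one row per a value with the Spearman rank correlation of
    median peak vs connection probability and the median-peak range
    (max - min over p), used to compare the sizes of the p and a effects.
    """
    from scipy.stats import spearmanr

    summ = scan.summary()
    out = []
    for a_val, grp in summ.groupby("a"):
        grp = grp.dropna(subset=["median_peak_hz"])
        if len(grp) >= 2:
            rho = spearmanr(
                grp["connection_probability"], grp["median_peak_hz"]
            ).statistic
            rng = grp["median_peak_hz"].max() - grp["median_peak_hz"].min()
        else:
            rho, rng = np.nan, np.nan
        out.append({"a": a_val, "spearman_p_vs_peak": rho, "peak_range_hz": rng})
    return pd.DataFrame(out)
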