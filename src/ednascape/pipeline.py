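"""End-to-end orchestration: fit all taxa, map the index, validate.

The stage order mirrors the assessment procedure: per-taxon model fits
on the eDNA table → per-reach detection-probability maps → thresholded
presence/absence → per-reach IBCH scores → comparison with kick-net
index values and habitat classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RiverNetwork
from .edith import (EDNASampleTable, EDITHPosterior, DetectionMap,
                    PriorConfig, MCMCConfig, fit_edith,
                    detection_probability, apply_presence_threshold,
                    presence_frame, default_production_threshold)
from .ibch import IBCHConfig, default_config, ibch_map, score_sites
from .validate import (ConfusionRecord, RegressionSummary, HabitatAssociation,
                       confusion_per_taxon, confusion_frame, mean_accuracy,
                       regress_measured_on_predicted, habitat_association)

__all__ = ["ValidationReport", "PipelineResult", "fit_all_taxa",
           "detection_maps", "run_pipeline", "evaluate"]


@dataclass
class ValidationReport:
    confusion: pd.DataFrame
    mean_accuracy_pct: float
    regression: RegressionSummary
    habitat: HabitatAssociation | None
    matched_index: pd.DataFrame | None = None  # site, predicted, measured


@dataclass
class PipelineResult:
    posteriors: dict[str, EDITHPosterior]
    maps: dict[str, DetectionMap]
    presence: pd.DataFrame  # reach × taxon
    ibch: pd.DataFrame  # reach_id, richness, ibch, status
    report: ValidationReport | None = None


def _taxon_seeds(seed: int, taxa: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(taxa))
    return {t: int(s) % (2 ** 31) for t, s in zip(taxa, state)}


def fit_all_taxa(data: EDNASampleTable, net: RiverNetwork,
                 priors: PriorConfig | None = None,
                 mcmc: MCMCConfig | None = None,
                 seed: int = 0, noise_model: str = "geometric",
                 calibration: float = 1.0) -> dict[str, EDITHPosterior]:
    """Independent per-taxon fits (taxa are modelled separately)."""
    seeds = _taxon_seeds(seed, data.taxa)
    return {t: fit_edith(data, t, net, priors=priors, mcmc=mcmc,
                         seed=seeds[t], noise_model=noise_model,
                         calibration=calibration)
            for t in data.taxa}


def detection_maps(posteriors: dict[str, EDITHPosterior], net: RiverNetwork,
                   p_star: float, prob_threshold: float = 0.5
                   ) -> dict[str, DetectionMap]:
    return {t: apply_presence_threshold(
        detection_probability(post, net, p_star), prob_threshold)
        for t, post in posteriors.items()}


def evaluate(presence: pd.DataFrame, ibch_df: pd.DataFrame,
             kicknet: pd.DataFrame, cfg: IBCHConfig,
             habitat: pd.Series | None = None,
             site_map: dict[str, str] | None = None) -> ValidationReport:
    """Compare predictions with kick-net observations and habitat classes.

    ``site_map`` maps kick-net site ids to network reach ids (identity
    when omitted).  Taxa are compared over the intersection of the
    predicted and observed taxon sets; the index regression uses the full
    records on both sides.
    """
    site_map = site_map or {str(s): str(s) for s in kicknet.index}
    missing = [s for s in kicknet.index if str(s) not in site_map]
    if missing:
        raise ValueError(f"kick-net site(s) without a reach match: {missing[:5]}")
    reach_of = {str(s): site_map[str(s)] for s in kicknet.index}
    bad = [r for r in reach_of.values() if r not in set(presence.index.astype(str))]
    if bad:
        raise ValueError(f"matched reach(es) absent from predictions: {bad[:5]}")

    # per-taxon confusion over the shared taxon set
    shared = [t for t in kicknet.columns if t in presence.columns]
    pred_at_sites = presence.loc[[reach_of[str(s)] for s in kicknet.index], shared]
    pred_at_sites.index = kicknet.index
    records = confusion_per_taxon(pred_at_sites.astype(bool),
                                  kicknet[shared].astype(bool))
    acc = mean_accuracy(records)

    # measured vs predicted IBCH at matched sites
    measured = score_sites(kicknet.astype(bool), cfg)["ibch"]
    pred_ibch = ibch_df.set_index("reach_id")["ibch"]
    predicted = pd.Series(
        [pred_ibch[reach_of[str(s)]] for s in kicknet.index],
        index=kicknet.index, dtype=float)
    reg = regress_measured_on_predicted(predicted.to_numpy(),
                                        measured.to_numpy(dtype=float))

    hab = None
    if habitat is not None:
        hab = habitat_association(pred_ibch.astype(float), habitat)
    matched = pd.DataFrame({"site": [str(s) for s in kicknet.index],
                            "predicted": predicted.to_numpy(),
                            "measured": measured.to_numpy(dtype=float)})
    return ValidationReport(confusion=confusion_frame(records),
                            mean_accuracy_pct=acc, regression=reg, habitat=hab,
                            matched_index=matched)


def run_pipeline(net: RiverNetwork, edna: EDNASampleTable,
                 kicknet: pd.DataFrame | None = None,
                 habitat: pd.Series | None = None,
                 ibch_cfg: IBCHConfig | None = None,
                 priors: PriorConfig | None = None,
                 mcmc: MCMCConfig | None = None,
                 seed: int = 0,
                 noise_model: str = "geometric",
                 calibration: float = 1.0,
                 p_star: float | None = None,
                 prob_threshold: float = 0.5,
                 site_map: dict[str, str] | None = None) -> PipelineResult:
    """Full assessment: fit → detection maps → IBCH map → validation."""
    priors = priors or PriorConfig()
    ibch_cfg = ibch_cfg or default_config()
    if p_star is None:
        p_star = default_production_threshold(priors)
    posteriors = fit_all_taxa(edna, net, priors=priors, mcmc=mcmc, seed=seed,
                              noise_model=noise_model, calibration=calibration)
    maps = detection_maps(posteriors, net, p_star, prob_threshold)
    presence = presence_frame(maps)
    ibch_df = ibch_map(maps, net, ibch_cfg)
    report = None
    if kicknet is not None:
        report = evaluate(presence, ibch_df, kicknet, ibch_cfg,
                          habitat=habitat, site_map=site_map)
    return PipelineResult(posteriors=posteriors, maps=maps, presence=presence,
                          ibch=ibch_df, report=report)
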