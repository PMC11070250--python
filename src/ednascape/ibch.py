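"""IBCH biotic index: scoring communities and mapping scores over networks.

The IBCH is a 0–20 macroinvertebrate index combining two ingredients:

* the *group indicator* GI (1–9) of the most sensitive indicator taxon
  present — 9 marks the most pollution-sensitive stonefly families — and
* the *variety class* CV (1–14), an ordinal class of total taxon
  richness, so that the weight of a sensitive find is modulated by the
  diversity around it.

The default score rule is the classic additive one, GI + CV − 1 clipped
to [0, 20]; a full 2-D (GI, CV) → score lookup table can be supplied
instead.  Scores are banded into five status classes (very good … bad).

The GI assignments, variety breakpoints and status bands shipped here are
synthetic stand-ins patterned on the public IBGN-style system (the exact
Swiss tables are not redistributed); every table is config-editable.
When counts are available (kick-net samples) an indicator taxon only
qualifies if it reaches ``min_abundance`` individuals; presence/absence
data (e.g. thresholded eDNA maps) qualify as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RiverNetwork

__all__ = [
    "IBCHConfig",
    "CommunityRecord",
    "default_config",
    "variety_class",
    "indicator_group",
    "ibch_score",
    "score_from_gi_cv",
    "status_class",
    "ibch_map",
]


# synthetic stand-in GI table (IBGN-style); GI 9 families are the classic
# sensitive stoneflies
DEFAULT_GI_MAP: dict[str, int] = {
    "Chloroperlidae": 9, "Perlidae": 9, "Perlodidae": 9, "Taeniopterygidae": 9,
    "Capniidae": 8, "Brachycentridae": 8, "Odontoceridae": 8, "Philopotamidae": 8,
    "Leuctridae": 7, "Glossosomatidae": 7, "Beraeidae": 7, "Goeridae": 7,
    "Leptophlebiidae": 7, "Polycentropodidae": 7,
    "Nemouridae": 6, "Lepidostomatidae": 6, "Sericostomatidae": 6, "Ephemeridae": 6,
    "Hydroptilidae": 5, "Heptageniidae": 5, "Potamanthidae": 5,
    "Leptoceridae": 4, "Psychomyiidae": 4, "Rhyacophilidae": 4,
    "Limnephilidae": 3, "Ephemerellidae": 3, "Hydropsychidae": 3, "Aphelocheiridae": 3,
    "Baetidae": 2, "Caenidae": 2, "Elmidae": 2, "Gammaridae": 2,
    "Chironomidae": 1, "Asellidae": 1, "Oligochaeta": 1, "Erpobdellidae": 1,
}

# (min_taxa, max_taxa, CV); None max = unbounded; IBGN-style breakpoints
DEFAULT_VARIETY_BREAKPOINTS: list[tuple[int, int | None, int]] = [
    (1, 3, 1), (4, 6, 2), (7, 9, 3), (10, 12, 4), (13, 16, 5),
    (17, 20, 6), (21, 24, 7), (25, 28, 8), (29, 32, 9), (33, 36, 10),
    (37, 40, 11), (41, 44, 12), (45, 49, 13), (50, None, 14),
]

# five equal-width status bands over 0..20 (min, max, label)
DEFAULT_STATUS_BANDS: list[tuple[int, int, str]] = [
    (0, 4, "bad"), (5, 8, "poor"), (9, 12, "moderate"),
    (13, 16, "good"), (17, 20, "very good"),
]

STATUS_LABELS = ["bad", "poor", "moderate", "good", "very good"]


@dataclass
class IBCHConfig:
    """IBCH scoring tables.

    ``score_table`` (optional) is a DataFrame with columns gi, cv, score
    overriding the additive GI + CV − 1 rule.
    """

    gi_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GI_MAP))
    variety_breakpoints: list[tuple[int, int | None, int]] = field(
        default_factory=lambda: list(DEFAULT_VARIETY_BREAKPOINTS))
    status_bands: list[tuple[int, int, str]] = field(
        default_factory=lambda: list(DEFAULT_STATUS_BANDS))
    score_table: pd.DataFrame | None = None
    min_abundance: int = 3

    def __post_init__(self) -> None:
        bad = {t: g for t, g in self.gi_map.items() if not 1 <= int(g) <= 9}
        if bad:
            raise ValueError(f"GI values outside 1..9: {bad}")
        # breakpoints must tile 1..inf without gaps or overlaps
        bps = sorted(self.variety_breakpoints)
        expect = 1
        for lo, hi, _cv in bps:
            if lo != expect:
                raise ValueError(f"variety breakpoints gap/overlap at {lo}")
            expect = (hi + 1) if hi is not None else None
            if expect is None:
                break
        if expect is not None:
            raise ValueError("variety breakpoints do not cover all richness values")
        covered = set()
        for lo, hi, _label in sorted(self.status_bands):
            covered.update(range(lo, hi + 1))
        if covered != set(range(0, 21)):
            raise ValueError("status bands must partition scores 0..20")

    def taxa(self) -> list[str]:
        return list(self.gi_map)


def default_config() -> IBCHConfig:
    return IBCHConfig()


@dataclass
class CommunityRecord:
    """Taxa observed at one unit (reach or site), optionally with counts."""

    unit_id: str
    taxa: set[str]
    abundances: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.abundances is not None:
            extra = set(self.abundances) - set(self.taxa)
            if extra:
                raise ValueError(f"abundances for taxa not in record: {extra}")
            if any(v < 1 for v in self.abundances.values()):
                raise ValueError("abundances must be >= 1")


def variety_class(n_taxa: int, cfg: IBCHConfig) -> int:
    """Variety class CV from taxon richness (0 iff the community is empty)."""
    if n_taxa < 0:
        raise ValueError("n_taxa must be non-negative")
    if n_taxa == 0:
        return 0
    for lo, hi, cv in cfg.variety_breakpoints:
        if n_taxa >= lo and (hi is None or n_taxa <= hi):
            return int(cv)
    raise RuntimeError("unreachable: breakpoints validated to cover N+")


def indicator_group(rec: CommunityRecord, cfg: IBCHConfig) -> int:
    """Highest GI among qualifying indicator taxa present (0 if none).

    With abundances, a taxon qualifies only at >= ``cfg.min_abundance``
    individuals (kick-net robustness rule); pure presence data qualify.
    """
    best = 0
    for t in rec.taxa:
        gi = cfg.gi_map.get(t)
        if gi is None:
            continue
        if rec.abundances is not None:
            if rec.abundances.get(t, 0) < cfg.min_abundance:
                continue
        best = max(best, int(gi))
    return best


def score_from_gi_cv(gi: int, cv: int, cfg: IBCHConfig) -> int:
    """Combine GI and CV into the 0–20 score (table lookup or additive rule)."""
    if cv == 0:
        return 0
    if cfg.score_table is not None:
        tab = cfg.score_table
        row = tab[(tab["gi"] == gi) & (tab["cv"] == cv)]
        if len(row) != 1:
            raise KeyError(f"score table has no entry for GI={gi}, CV={cv}")
        return int(row["score"].iloc[0])
    return int(np.clip(gi + cv - 1, 0, 20))


def ibch_score(rec: CommunityRecord, cfg: IBCHConfig) -> int:
    """IBCH score of a community (0 when empty)."""
    n = len(rec.taxa)
    return score_from_gi_cv(indicator_group(rec, cfg), variety_class(n, cfg), cfg)


def status_class(score: int, cfg: IBCHConfig) -> str:
    """Ecological status label for a score."""
    if not 0 <= score <= 20:
        raise ValueError(f"score {score} outside 0..20")
    for lo, hi, label in cfg.status_bands:
        if lo <= score <= hi:
            return label
    raise RuntimeError("unreachable: bands validated to partition 0..20")


def ibch_map(maps: dict, net: RiverNetwork, cfg: IBCHConfig) -> pd.DataFrame:
    """Score every reach of the network from thresholded detection maps.

    ``maps`` is taxon → DetectionMap (thresholded).  Taxa absent from the
    GI table count towards richness but not towards the indicator group.
    Returns a frame with one row per reach: reach_id, richness, ibch,
    status (space-filling: every reach is scored).
    """
    from .edith import presence_frame
    pres = presence_frame(maps)
    reach_ids = [str(r) for r in net.ids]
    missing = set(reach_ids) ^ set(pres.index)
    if missing:
        raise ValueError(
            f"detection maps do not cover the network reach set: {sorted(missing)[:5]}")
    pres = pres.loc[reach_ids]
    rows = []
    for rid, row in pres.iterrows():
        taxa = set(row.index[row.to_numpy(dtype=bool)])
        score = ibch_score(CommunityRecord(unit_id=str(rid), taxa=taxa), cfg)
        rows.append({"reach_id": str(rid), "richness": len(taxa),
                     "ibch": score, "status": status_class(score, cfg)})
    return pd.DataFrame(rows)


def score_sites(presence: pd.DataFrame, cfg: IBCHConfig,
                abundances: pd.DataFrame | None = None) -> pd.DataFrame:
    """IBCH per row of a unit × taxon presence table (e.g. kick-net sites)."""
    rows = []
    for uid, row in presence.iterrows():
        taxa = set(row.index[row.to_numpy(dtype=bool)])
        ab = None
        if abundances is not None:
            ab = {t: int(abundances.loc[uid, t]) for t in taxa
                  if t in abundances.columns and abundances.loc[uid, t] >= 1}
        score = ibch_score(CommunityRecord(str(uid), taxa, ab), cfg)
        rows.append({"unit_id": str(uid), "richness": len(taxa),
                     "ibch": score, "status": status_class(score, cfg)})
    return pd.DataFrame(rows).set_index("unit_id")
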