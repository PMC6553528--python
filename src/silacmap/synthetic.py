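"""Seeded synthetic SILAC AP-MS datasets with known ground truth.

The generator emulates the statistical structure a bait-vs-control SILAC
pulldown analysis assumes, at the peptide level:

* protein total intensities are log-normal (``log10 I ~ Normal(mean, sd)``);
* background proteins carry a true log2 H/L ratio drawn from
  ``Normal(0, sigma(I))``, spiked (true interactor) proteins from
  ``Normal(log2_effect, sigma(I))``, where the spread
  ``sigma(I) = noise_sd_base + noise_sd_slope * max(0, mean - log10 I)``
  widens for faint proteins — the intensity-dependence the intensity-binned
  outlier statistic exists to handle;
* each protein's intensity is split across its peptides by a symmetric
  Dirichlet draw, and each peptide channel independently drops out with a
  probability that rises for faint peptides — which is how proteins with
  measured intensities but no computable ratio arise;
* replicates are fully independent draws of the same ground truth.

Aggregation to protein groups mirrors common upstream behaviour: channel
intensities are summed over peptides, the protein ratio is the median of
peptide-level H/L ratios over peptides observed in both channels, and the
ratio is withheld (null) when fewer than ``min_ratio_count`` peptides
qualify.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

PEPTIDE_COLUMNS = ["protein_id", "peptide_id", "replicate", "intensity_h", "intensity_l"]

PROTEIN_GROUP_COLUMNS = [
    "protein_id",
    "gene_name",
    "replicate",
    "intensity_h",
    "intensity_l",
    "ratio_hl",
    "ratio_count",
    "ratio_provenance",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic AP-MS experiment.

    Defaults describe a mid-sized pulldown: ~1000 co-purifying background
    proteins, 20 true interactors enriched 16-fold (log2 effect 4) in the
    heavy channel, intensities centred at 1e7 spanning roughly 1e5–1e9,
    ratio noise growing from 0.3 (bright) to ~0.75 (faint) log2 units, five
    peptides per protein on average, and a per-channel dropout probability
    of 0.1 rising by 0.1 per decade below the intensity centre.
    """

    n_background: int = 1000
    n_spiked: int = 20
    log2_effect: float = 4.0
    intensity_log10_mean: float = 7.0
    intensity_log10_sd: float = 1.0
    noise_sd_base: float = 0.3
    noise_sd_slope: float = 0.15
    peptides_per_protein_mean: float = 5.0
    dropout_base: float = 0.1
    dropout_slope: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_background", "n_spiked"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("intensity_log10_sd", "noise_sd_base", "noise_sd_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("dropout_base", "dropout_slope"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.peptides_per_protein_mean < 1:
            raise ConfigError(
                f"peptides_per_protein_mean must be >= 1, got {self.peptides_per_protein_mean}"
            )
        if self.n_replicates < 1:
            raise ConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")

    def to_dict(self) -> dict:
        return asdict(self)


def _protein_ids(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    width = max(4, len(str(max(config.n_background, config.n_spiked, 1))))
    background = np.array([f"BG{i:0{width}d}" for i in range(1, config.n_background + 1)])
    spiked = np.array([f"SP{i:0{width}d}" for i in range(1, config.n_spiked + 1)])
    return background, spiked


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one seeded experiment.

    Returns ``(observations, truth)``: a peptide-observation table with
    columns :data:`PEPTIDE_COLUMNS` and a ground-truth table with columns
    ``protein_id`` and ``label`` (``"background"`` or ``"spiked"``).
    Identical ``config`` (including seed) reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    background, spiked = _protein_ids(config)
    protein_ids = np.concatenate([background, spiked])
    effects = np.concatenate(
        [np.zeros(len(background)), np.full(len(spiked), config.log2_effect)]
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "label": ["background"] * len(background) + ["spiked"] * len(spiked),
        }
    )
    n_prot = len(protein_ids)
    if n_prot == 0:
        empty = pd.DataFrame(columns=PEPTIDE_COLUMNS)
        return empty, truth

    frames = []
    for rep in range(1, config.n_replicates + 1):
        log10_i = rng.normal(config.intensity_log10_mean, config.intensity_log10_sd, n_prot)
        sigma = config.noise_sd_base + config.noise_sd_slope * np.maximum(
            0.0, config.intensity_log10_mean - log10_i
        )
        log2_ratio = rng.normal(effects, sigma)
        n_peptides = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0, n_prot)

        # Dirichlet split of each protein's intensity via normalised gammas.
        total_peps = int(n_peptides.sum())
        gammas = rng.gamma(1.0, 1.0, total_peps)
        owner = np.repeat(np.arange(n_prot), n_peptides)
        sums = np.zeros(n_prot)
        np.add.at(sums, owner, gammas)
        weights = gammas / sums[owner]
        pep_total = (10.0 ** log10_i)[owner] * weights

        frac_h = (2.0 ** log2_ratio)[owner] / (1.0 + (2.0 ** log2_ratio)[owner])
        intensity_h = pep_total * frac_h
        intensity_l = pep_total * (1.0 - frac_h)

        with np.errstate(divide="ignore"):
            low_term = np.maximum(
                0.0, config.intensity_log10_mean - np.log10(np.maximum(pep_total, 1e-300))
            )
        p_drop = np.clip(config.dropout_base + config.dropout_slope * low_term, 0.0, 1.0)
        intensity_h = np.where(rng.random(total_peps) < p_drop, 0.0, intensity_h)
        intensity_l = np.where(rng.random(total_peps) < p_drop, 0.0, intensity_l)

        pep_rank = np.concatenate([np.arange(1, k + 1) for k in n_peptides])
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": protein_ids[owner],
                    "peptide_id": [
                        f"{pid}_pep{j}" for pid, j in zip(protein_ids[owner], pep_rank)
                    ],
                    "replicate": rep,
                    "intensity_h": intensity_h,
                    "intensity_l": intensity_l,
                }
            )
        )
    observations = pd.concat(frames, ignore_index=True)
    return observations[PEPTIDE_COLUMNS], truth


def aggregate_to_protein_groups(
    observations: pd.DataFrame,
    min_ratio_count: int = 2,
) -> pd.DataFrame:
    """Aggregate peptide observations into per-replicate protein groups.

    Channel intensities are summed over all peptides of a protein; the
    protein H/L ratio is the median over peptides observed in both channels,
    withheld when fewer than ``min_ratio_count`` such peptides exist.
    """
    if min_ratio_count < 1:
        raise ConfigError(f"min_ratio_count must be >= 1, got {min_ratio_count}")
    if observations.empty:
        return pd.DataFrame(columns=PROTEIN_GROUP_COLUMNS)
    obs = observations
    keys = ["protein_id", "replicate"]
    sums = obs.groupby(keys, sort=True)[["intensity_h", "intensity_l"]].sum()

    both = obs.loc[(obs["intensity_h"] > 0) & (obs["intensity_l"] > 0)].copy()
    both["pep_ratio"] = both["intensity_h"] / both["intensity_l"]
    ratio_stats = both.groupby(keys, sort=True)["pep_ratio"].agg(["median", "count"])

    table = sums.join(ratio_stats, how="left").reset_index()
    table["count"] = table["count"].fillna(0).astype(int)
    table = table.rename(columns={"median": "ratio_hl", "count": "ratio_count"})
    below = table["ratio_count"] < min_ratio_count
    table.loc[below, "ratio_hl"] = np.nan
    table["ratio_provenance"] = np.where(table["ratio_hl"].notna(), "computed", "none")
    table["gene_name"] = table["protein_id"]
    return table[PROTEIN_GROUP_COLUMNS]
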