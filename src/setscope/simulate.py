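"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_counts` — a genes x cells UMI matrix with identity
  labels and a designated gene set.  Gene baseline means are log-normal,
  counts are negative binomial (mean/dispersion parameterization,
  variance = mean + mean^2/dispersion — the standard droplet scRNA-seq
  noise model).  Optionally a chosen identity has a random subset of set
  genes upregulated by a fixed fold, the alternative the enrichment
  pipeline should recover.

* :func:`simulate_spots` — per-cell RNAscope object tables.  Cells belong
  to types with per-channel molecule means (defaults echo a preoptic-area
  census: a small Gal/Calcr population with high Magel2, Gal-only and
  Calcr-only populations, and a large background population); true
  per-cell molecule counts are Poisson; molecules emit either as
  individual signals or merge into one cluster per cell and channel with
  probability ``cluster_prob``; a matching no-probe-control table carries
  folded-Gaussian background maxima.

All randomness flows from the single integer seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CountMatrix, GeneSet

__all__ = ["ScSimConfig", "SpotSimConfig", "simulate_counts", "simulate_spots"]


@dataclass
class ScSimConfig:
    """Single-cell count simulation parameters.

    The default alternative plants 20 of a 74-gene set at fold 4 in one
    of 10 identities of 200 cells each; ``planted_identity=None`` gives
    the matched null (no planted effect anywhere).
    """

    n_genes: int = 1000
    n_identities: int = 10
    cells_per_identity: int = 200
    baseline_mean_log_mu: float = -1.0  # natural-log scale of gene means
    baseline_mean_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    set_size: int = 74
    planted_identity: str | None = None
    planted_set_fraction: float = 20.0 / 74.0
    planted_fold: float = 4.0
    seed: int = 0

    def identity_labels(self) -> list[str]:
        return [f"ident{i:02d}" for i in range(self.n_identities)]

    @classmethod
    def default_alternative(cls, seed: int = 0) -> "ScSimConfig":
        return cls(planted_identity="ident05", seed=seed)


@dataclass
class SpotSimConfig:
    """RNAscope signal simulation parameters.

    ``cell_types`` maps each type label to (proportion, per-channel
    molecule mean); proportions must sum to 1.  Intensities are in
    arbitrary units matching the calibration the quantifier consumes.
    """

    cell_types: list[tuple[str, float, dict[str, float]]] = field(
        default_factory=lambda: [
            ("Gal/Calcr", 0.05, {"Gal": 8.0, "Calcr": 6.0, "Magel2": 5.8}),
            ("Gal", 0.06, {"Gal": 6.0, "Calcr": 0.2, "Magel2": 3.0}),
            ("Calcr", 0.05, {"Gal": 0.2, "Calcr": 5.0, "Magel2": 3.3}),
            ("other", 0.84, {"Gal": 0.1, "Calcr": 0.1, "Magel2": 1.5}),
        ]
    )
    n_cells: int = 1000
    single_intensity_mean: float = 300.0
    single_intensity_sd: float = 30.0
    background: float = 20.0
    cluster_prob: float = 0.3
    n_control_cells: int = 200
    control_noise_sd: float = 10.0
    animal_id: str = "A1"
    section_id: str = "S1"
    condition: str = "control"
    seed: int = 0


def simulate_counts(
    cfg: ScSimConfig,
) -> tuple[CountMatrix, pd.DataFrame, GeneSet, dict]:
    """Draw a count matrix, annotation, gene set and ground-truth record."""
    if cfg.set_size > cfg.n_genes:
        raise ValueError("set_size cannot exceed n_genes")
    if not 0.0 <= cfg.planted_set_fraction <= 1.0:
        raise ValueError("planted_set_fraction must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    identities = cfg.identity_labels()
    if cfg.planted_identity is not None and cfg.planted_identity not in identities:
        raise ValueError(
            f"planted identity {cfg.planted_identity!r} not among "
            f"{identities[0]}..{identities[-1]}"
        )

    baseline = rng.lognormal(
        cfg.baseline_mean_log_mu, cfg.baseline_mean_log_sd, size=cfg.n_genes
    )
    set_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.set_size, replace=False))
    set_genes = [genes[i] for i in set_idx]
    origins = rng.choice(["MEG", "PEG"], size=cfg.set_size)

    planted_genes: list[str] = []
    planted_idx = np.array([], dtype=int)
    if cfg.planted_identity is not None and cfg.planted_fold > 1.0:
        n_planted = int(round(cfg.planted_set_fraction * cfg.set_size))
        planted_idx = rng.choice(set_idx, size=n_planted, replace=False)
        planted_genes = sorted(genes[i] for i in planted_idx)

    blocks = []
    cell_ids: list[str] = []
    labels: list[str] = []
    for ident in identities:
        mean = baseline.copy()
        if ident == cfg.planted_identity:
            mean[planted_idx] *= cfg.planted_fold
        shape = cfg.nb_dispersion
        lam = rng.gamma(
            shape,
            (mean / shape)[:, None],
            size=(cfg.n_genes, cfg.cells_per_identity),
        )
        blocks.append(rng.poisson(lam))
        start = len(cell_ids)
        cell_ids.extend(
            f"{ident}_c{start + j:05d}" for j in range(cfg.cells_per_identity)
        )
        labels.extend([ident] * cfg.cells_per_identity)

    values = sparse.csr_matrix(np.concatenate(blocks, axis=1))
    counts = CountMatrix(values=values, gene_ids=genes, cell_ids=cell_ids)
    annotation = pd.DataFrame({"cell_id": cell_ids, "identity": labels})
    gene_set = GeneSet(
        table=pd.DataFrame({"gene": set_genes, "origin": origins})
    )
    truth = {
        "planted_identity": cfg.planted_identity,
        "planted_genes": planted_genes,
        "planted_fold": cfg.planted_fold if planted_genes else 1.0,
        "set_genes": set_genes,
        "baseline_means": baseline.tolist(),
        "seed": cfg.seed,
    }
    return counts, annotation, gene_set, truth


def _emit_objects(
    rng: np.random.Generator,
    n_molecules: int,
    cfg: SpotSimConfig,
) -> list[float]:
    """Intensities of the objects a cell shows on one channel."""
    if n_molecules == 0:
        return []
    singles = rng.normal(
        cfg.single_intensity_mean, cfg.single_intensity_sd, size=n_molecules
    )
    singles = np.maximum(singles, 0.0)
    if n_molecules > 1 and rng.random() < cfg.cluster_prob:
        return [float(singles.sum() + cfg.background)]
    return [float(s + cfg.background) for s in singles]


def simulate_spots(
    cfg: SpotSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (signal table, control table, ground-truth molecule table)."""
    props = np.array([p for _, p, _ in cfg.cell_types], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"cell-type proportions sum to {props.sum()}, not 1")
    channels = sorted(
        {ch for _, _, means in cfg.cell_types for ch in means}
    )
    rng = np.random.default_rng(cfg.seed)
    type_labels = [label for label, _, _ in cfg.cell_types]
    type_means = {label: means for label, _, means in cfg.cell_types}
    assignment = rng.choice(len(type_labels), size=cfg.n_cells, p=props)

    signal_rows = []
    truth_rows = []
    for i in range(cfg.n_cells):
        cell_id = f"cell{i:05d}"
        label = type_labels[assignment[i]]
        truth: dict = {
            "cell_id": cell_id,
            "animal_id": cfg.animal_id,
            "section_id": cfg.section_id,
            "condition": cfg.condition,
            "cell_type": label,
        }
        for ch in channels:
            mean = type_means[label].get(ch, 0.0)
            n_mol = int(rng.poisson(mean))
            truth[ch] = n_mol
            for intensity in _emit_objects(rng, n_mol, cfg):
                signal_rows.append(
                    {
                        "cell_id": cell_id,
                        "section_id": cfg.section_id,
                        "animal_id": cfg.animal_id,
                        "condition": cfg.condition,
                        "channel": ch,
                        "integral_intensity": intensity,
                    }
                )
        truth_rows.append(truth)

    control_rows = []
    for j in range(cfg.n_control_cells):
        for ch in channels:
            control_rows.append(
                {
                    "cell_id": f"ctrl{j:05d}",
                    "channel": ch,
                    "max_intensity": float(
                        abs(rng.normal(0.0, cfg.control_noise_sd))
                        + cfg.background
                    ),
                }
            )

    signals = pd.DataFrame(
        signal_rows,
        columns=[
            "cell_id",
            "section_id",
            "animal_id",
            "condition",
            "channel",
            "integral_intensity",
        ],
    )
    controls = pd.DataFrame(
        control_rows, columns=["cell_id", "channel", "max_intensity"]
    )
    truth_table = pd.DataFrame(truth_rows)
    return signals, controls, truth_table
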