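"""Generator of expression cohorts with a planted pathway-ROR correlation.

Emulates the study's 20-cohort design: one genes x samples matrix per
cancer type, each type carrying an observed irAE reporting odds ratio.
For every planted gene set a per-type latent activity

    s_t = rho * z_t + sqrt(1 - rho^2) * eps_t,   eps_t ~ N(0, 1)

is drawn, where z_t is the standardized log of the type's planted ROR, so
the median activity of the set's member genes correlates with the RORs at
the requested rho (attenuated only by within-type sampling noise).
Member genes are shifted by ``effect * s_t`` on top of N(0, sigma) noise;
all other genes are pure noise.  Since downstream scoring is rank-based,
the Gaussian marginal is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..mechanism import CohortExpression, write_expression_tsv, write_gmt


@dataclass
class ExpressionGeneratorConfig:
    """Planted structure of the synthetic expression bundle.

    Defaults mirror the study scale: 20 cancer-type cohorts, per-type
    RORs spanning roughly 0.8-25 (the observed per-cancer-type range),
    one positively and one negatively correlated planted pathway plus
    uncorrelated decoy sets.
    """

    n_cancer_types: int = 20
    samples_per_type: int = 25
    n_genes: int = 400
    set_size: int = 30
    n_decoy_sets: int = 8
    planted_sets: dict[str, float] = field(
        default_factory=lambda: {
            "IFNG_SECRETION_REGULATION": 0.8,
            "DOPAMINE_RECEPTOR_SIGNALING": -0.6,
        }
    )
    effect: float = 1.0
    sigma: float = 1.0
    planted_rors: list[float] | None = None  # default: log-spaced 0.8..25
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cancer_types < 5:
            raise ValueError("need >= 5 cancer types for a meaningful correlation")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name, rho in self.planted_sets.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"{name}: |rho| must be <= 1")
        needed = (len(self.planted_sets) + self.n_decoy_sets) * self.set_size
        if needed > self.n_genes:
            raise ValueError("not enough genes for the requested gene sets")


def generate_expression(
    config: ExpressionGeneratorConfig,
) -> tuple[list[CohortExpression], dict[str, set[str]], dict]:
    """Draw the cohorts, gene sets and ground-truth manifest in memory."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, S, G = config.n_cancer_types, config.samples_per_type, config.n_genes
    genes = [f"G{i:04d}" for i in range(1, G + 1)]
    types = [f"CT{t:02d}" for t in range(1, T + 1)]

    if config.planted_rors is not None:
        if len(config.planted_rors) != T:
            raise ValueError("planted_rors length must equal n_cancer_types")
        rors = np.asarray(config.planted_rors, dtype=float)
    else:
        rors = np.exp(np.linspace(np.log(0.8), np.log(25.0), T))
        rng.shuffle(rors)
    z = np.log(rors)
    z = (z - z.mean()) / z.std()

    # disjoint member blocks: planted sets first, then decoys
    gene_sets: dict[str, set[str]] = {}
    cursor = 0
    latents: dict[str, np.ndarray] = {}
    for name, rho in config.planted_sets.items():
        gene_sets[name] = set(genes[cursor: cursor + config.set_size])
        cursor += config.set_size
        eps = rng.standard_normal(T)
        latents[name] = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
    for k in range(1, config.n_decoy_sets + 1):
        name = f"DECOY_SET_{k:02d}"
        gene_sets[name] = set(genes[cursor: cursor + config.set_size])
        cursor += config.set_size
        latents[name] = rng.standard_normal(T)  # rho = 0

    member_shift = np.zeros((G, T))
    gene_index = {g: i for i, g in enumerate(genes)}
    for name, members in gene_sets.items():
        rows = [gene_index[g] for g in members]
        member_shift[rows, :] += config.effect * latents[name][None, :]

    cohorts = []
    for t, ct in enumerate(types):
        noise = rng.normal(0.0, config.sigma, size=(G, S))
        m = noise + member_shift[:, [t]]
        cohorts.append(
            CohortExpression(
                cancer_type=ct,
                matrix=pd.DataFrame(m, index=genes,
                                    columns=[f"{ct}_S{j:03d}" for j in range(1, S + 1)]),
                observed_ror=float(rors[t]),
            )
        )
    manifest = {
        "seed": config.seed,
        "planted_rors": {ct: float(r) for ct, r in zip(types, rors)},
        "planted_rho": dict(config.planted_sets),
        "decoy_sets": [n for n in gene_sets if n.startswith("DECOY_")],
        "set_members": {n: sorted(s) for n, s in gene_sets.items()},
        "config": {k: v for k, v in asdict(config).items() if not isinstance(v, dict)},
    }
    return cohorts, gene_sets, manifest


def generate_expression_bundle(
    config: ExpressionGeneratorConfig, out_dir: str | Path
) -> dict:
    """Write TSV matrices, the GMT file and the manifest to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohorts, gene_sets, manifest = generate_expression(config)
    for co in cohorts:
        write_expression_tsv(co, out_dir / f"{co.cancer_type}.tsv")
    write_gmt(gene_sets, out_dir / "gene_sets.gmt")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
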