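"""End-to-end orchestration: generate -> fit -> update -> sweep -> scale.

``run_full_analysis`` executes the whole workflow from a single seeded
configuration and writes every artifact as delimited text plus a JSON
manifest.  All randomness derives from the one master seed through spawned
seed sequences, so a rerun with the same configuration reproduces every
number; each output file carries a header naming the seed and the
configuration hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .belief import surface_grid
from .cohort import (
    CohortConfig,
    TrialDesign,
    default_cohort_config,
    generate_cohort,
    write_cohort,
)
from .elicit import fit_cohort
from .mds import axis_loadings, belief_vectors, scale_vectors
from .posterior import DEFAULT_DRAWS, WORTHWHILE_OR, trial_size_sweep

__all__ = ["RunConfig", "run_full_analysis", "load_config"]

logger = logging.getLogger("vetelicit")

#: Per-arm trial sizes swept by default: 30 to 1000 infected cows per arm.
DEFAULT_SIZES = (30, 50, 250, 500, 750, 1000)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    seed: int = 0
    n_practices: int = 5
    vets_per_practice: tuple[int, ...] = (4, 5, 5, 5, 5)
    sizes: tuple[int, ...] = DEFAULT_SIZES
    threshold: float = WORTHWHILE_OR
    n_draws: int = DEFAULT_DRAWS
    assumed_theta1: float = 0.5
    surface_resolution: int = 100
    outdir: str = "vetelicit-run"

    def cohort_config(self, seed: int) -> CohortConfig:
        base = default_cohort_config(seed=seed)
        if (self.n_practices, tuple(self.vets_per_practice)) != (
            base.n_practices,
            base.vets_per_practice,
        ):
            mixes = (base.archetype_mix * self.n_practices)[: self.n_practices]
            base = CohortConfig(
                n_practices=self.n_practices,
                vets_per_practice=tuple(self.vets_per_practice),
                archetype_mix=mixes,
                seed=seed,
            )
        return base

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vets_per_practice"] = list(d["vets_per_practice"])
        d["sizes"] = list(d["sizes"])
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("vets_per_practice", "sizes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _tag(config: RunConfig) -> str:
    return f"seed={config.seed} config={config.digest()} vetelicit={__version__}"


def _write(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, index=False)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole workflow and write artifacts; returns the manifest.

    Stages: synthetic cohort generation; per-expert beta fits (failures
    isolated and reported, never silently dropped); joint-prior surface
    grids; the null-effect trial-size sweep with convinced counts; classical
    scaling with eigenvalues, goodness of fit and axis loadings.
    """
    if config.n_practices < 1 or sum(config.vets_per_practice) < 1:
        raise ValueError("cohort must contain at least one expert")
    if len(config.sizes) == 0:
        raise ValueError("sizes must be non-empty")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = _tag(config)

    ss = np.random.SeedSequence(config.seed)
    seed_cohort, seed_sweep = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)
    )

    # --- cohort -----------------------------------------------------------
    records = generate_cohort(config.cohort_config(seed_cohort))
    write_cohort(records, out / "cohort.csv", header_note=tag)
    logger.info("generated cohort: %d experts", len(records))

    # --- fits -------------------------------------------------------------
    fit = fit_cohort(records)
    fit_rows = []
    for pair in fit.pairs:
        f1 = fit.theta1_fits[pair.expert_id]
        f3 = fit.theta3_fits[pair.expert_id]
        fit_rows.append(
            {
                "expert_id": pair.expert_id,
                "alpha1": pair.theta1_prior.alpha,
                "beta1": pair.theta1_prior.beta,
                "alpha3": pair.theta3_prior.alpha,
                "beta3": pair.theta3_prior.beta,
                "objective1": f1.objective,
                "objective3": f3.objective,
                "converged": f1.converged and f3.converged,
                "p_worse": pair.p_worse,
            }
        )
    _write(pd.DataFrame(fit_rows), out / "fitted_priors.csv", tag)
    logger.info("fitted priors: %d ok, %d failed", len(fit.pairs), len(fit.failures))

    # --- joint-prior surfaces --------------------------------------------
    surf_dir = out / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    for pair in fit.pairs:
        surf = surface_grid(pair, resolution=config.surface_resolution)
        grid = pd.DataFrame(surf.density, index=surf.centres, columns=surf.centres)
        with open(surf_dir / f"joint_{pair.expert_id}.csv", "w") as fh:
            fh.write(f"# {tag} expert={pair.expert_id} phi={surf.normaliser:.6g}\n")
            grid.to_csv(fh, index_label="theta1")

    # --- trial-size sweep -------------------------------------------------
    design = TrialDesign(
        n_per_arm=max(config.sizes),
        assumed_theta1=config.assumed_theta1,
        null_effect=True,
    )
    sweep = trial_size_sweep(
        fit.pairs,
        sizes=config.sizes,
        design=design,
        threshold=config.threshold,
        n_draws=config.n_draws,
        seed=seed_sweep,
    )
    _write(sweep.table, out / "sweep.csv", tag)
    _write(sweep.counts, out / "sweep_counts.csv", tag)
    logger.info("sweep done: %d sizes x %d experts", len(sweep.counts), len(fit.pairs))

    # --- classical scaling -------------------------------------------------
    scaling = scale_vectors(belief_vectors(records))
    coords = pd.DataFrame(
        scaling.coordinates,
        index=pd.Index(scaling.expert_ids, name="expert_id"),
        columns=[f"axis{k+1}" for k in range(scaling.rank)],
    )
    _write(coords.reset_index(), out / "mds_coordinates.csv", tag)
    eig = pd.DataFrame(
        {
            "dimension": np.arange(1, scaling.eigenvalues.size + 1),
            "eigenvalue": scaling.eigenvalues,
            "gof": scaling.gof,
        }
    )
    _write(eig, out / "mds_eigenvalues.csv", tag)
    load_rows = []
    for dim in range(min(3, scaling.rank)):
        s = axis_loadings(scaling, dim)
        for pos, val in s.items():
            load_rows.append({"axis": dim + 1, "position": pos, "loading": val})
    _write(pd.DataFrame(load_rows), out / "mds_loadings.csv", tag)

    manifest = {
        "package": "vetelicit",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "derived_seeds": {"cohort": seed_cohort, "sweep": seed_sweep},
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_experts": len(records),
        "n_fitted": len(fit.pairs),
        "fit_failures": [{"expert_id": e, "reason": r} for e, r in fit.failures],
        "convinced_counts": sweep.counts.to_dict(orient="records"),
        "gof_first3": float(scaling.gof[2]) if scaling.gof.size >= 3 else None,
        "files": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
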