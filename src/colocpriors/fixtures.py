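"""Deterministic synthetic-data bundles for every input format.

A fixture bundle is a self-consistent set of files — summary-statistic
pairs with known causal variants, an LD matrix, a significant-eQTL table
for density estimation, ABC / constraint / per-SNP-variance tables over
the same coordinates, and a manifest recording the ground truth — so the
full pipeline and the test suite run without any external download.

Everything is derived from a single seeded generator: the same spec and
seed always produce byte-identical files (no timestamps are written).
Ground truth lives only in the manifest, never in file names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .gwas_simulator import SimConfig, SimulationError, simulate_haplotypes, simulate_pair
from .prior_sources import DENSITY_GRID_SIZE, DistanceDensity
from .region_data import write_ld, write_sumstats

__all__ = ["FixtureSpec", "make_fixture_bundle", "shape_density", "PRESETS"]

DENSITY_SHAPES = ("laplace_at_tss", "bimodal", "uniform")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture bundle.

    ``density_shape`` selects the ground-truth distribution of causal
    variants around the TSS; ``polyfun_coverage`` is the fraction of
    variants given a per-SNP variance entry.
    """

    seed: int = 0
    n_genes: int = 2
    n_variants_per_region: int = 120
    density_shape: str = "laplace_at_tss"
    abc_enhancers_per_gene: int = 3
    gnocchi_region_size: int = 1000
    polyfun_coverage: float = 0.8
    n_eqtl_records: int = 400
    window: int = 500_000
    ld_decay: float = 0.9

    def __post_init__(self):
        if self.density_shape not in DENSITY_SHAPES:
            raise ValueError(f"density_shape must be one of {DENSITY_SHAPES}")
        if not 0.0 <= self.polyfun_coverage <= 1.0:
            raise ValueError("polyfun_coverage must lie in [0, 1]")
        for name in ("n_genes", "n_variants_per_region", "abc_enhancers_per_gene",
                     "gnocchi_region_size", "n_eqtl_records"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: CLI presets: (spec overrides) keyed by name.
PRESETS: Dict[str, dict] = {
    "smoke": {"n_genes": 1, "n_variants_per_region": 60, "n_eqtl_records": 120},
    "simulation-study": {"n_genes": 3, "n_variants_per_region": 300, "ld_decay": 0.95},
    "benchmark": {"n_genes": 5, "n_variants_per_region": 120},
}


def shape_density(shape: str, window: int = 500_000, scale: float = 10_000.0) -> DistanceDensity:
    """Analytic ground-truth density on the standard 512-point grid.

    * ``laplace_at_tss`` — Laplace(0, scale): causal variants concentrate
      tightly around the TSS, the pattern seen for top whole-blood eQTLs
      (default scale 10 kb puts half the mass within ~7 kb of the TSS).
    * ``bimodal`` — an even mixture of two Laplace peaks at +/-150 kb.
    * ``uniform`` — no positional information.
    """
    grid = np.linspace(-window, window, DENSITY_GRID_SIZE)
    if shape == "laplace_at_tss":
        dens = np.exp(-np.abs(grid) / scale) / (2.0 * scale)
    elif shape == "bimodal":
        dens = 0.5 * (
            np.exp(-np.abs(grid - 150_000) / scale) + np.exp(-np.abs(grid + 150_000) / scale)
        ) / (2.0 * scale)
    elif shape == "uniform":
        dens = np.full(DENSITY_GRID_SIZE, 1.0 / (2.0 * window))
    else:
        raise ValueError(f"unknown density shape {shape!r}")
    return DistanceDensity(
        grid=grid, density=dens, bandwidth=max(scale, 1.0), window=window,
        source=f"synthetic-{shape}",
    )


def _sample_distances(shape: str, n: int, rng: np.random.Generator,
                      window: int, scale: float = 10_000.0) -> np.ndarray:
    if shape == "laplace_at_tss":
        d = rng.laplace(0.0, scale, size=n)
    elif shape == "bimodal":
        centre = rng.choice([-150_000.0, 150_000.0], size=n)
        d = centre + rng.laplace(0.0, scale, size=n)
    else:
        d = rng.uniform(-window, window, size=n)
    return np.clip(d, -window, window)


def make_fixture_bundle(spec: FixtureSpec, outdir) -> dict:
    """Write a mutually consistent fixture bundle and return its manifest.

    Per gene: a TSS/strand assignment, variant positions in a +/-window
    region, an LD matrix, an H3 and an H4 summary-statistic pair (causal
    variants drawn from the shape density), plus ABC, constraint and
    per-SNP-variance tables over the same coordinates.  One pooled
    significant-eQTL table supports density estimation.  The manifest
    (JSON) records seed, spec, file names and all ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    density = shape_density(spec.density_shape, spec.window)

    manifest: dict = {
        "spec": asdict(spec),
        "genes": {},
        "files": {},
    }

    # pooled eQTL table for density estimation (pseudo-genes, one row each)
    eqtl_rows = []
    for k in range(spec.n_eqtl_records):
        tss = int(rng.integers(1_000_000, 200_000_000))
        strand = "+" if rng.random() < 0.5 else "-"
        d = float(_sample_distances(spec.density_shape, 1, rng, spec.window)[0])
        pos = tss + int(round(d)) if strand == "+" else tss - int(round(d))
        # log-uniform significant p-values
        p = 10.0 ** rng.uniform(-30, np.log10(5e-8))
        eqtl_rows.append(
            {"gene": f"EG{k:05d}", "snp": f"ers{k:05d}", "chrom": "1",
             "pos": max(pos, 1), "tss": tss, "strand": strand, "p": p}
        )
    eqtl_path = outdir / "eqtl_significant.tsv"
    pd.DataFrame(eqtl_rows).to_csv(eqtl_path, sep="\t", index=False, float_format="%.10g")
    manifest["files"]["eqtl_table"] = eqtl_path.name

    abc_rows, gnocchi_rows, polyfun_rows = [], [], []
    for g in range(spec.n_genes):
        gene = f"GENE{g}"
        chrom = str(g + 1)
        tss = 1_000_000 + spec.window
        strand = "+" if rng.random() < 0.5 else "-"
        q = spec.n_variants_per_region
        positions = np.sort(
            rng.choice(np.arange(tss - spec.window, tss + spec.window), size=q, replace=False)
        ).astype(np.int64)

        config = SimConfig(n_variants=q, ld_decay=spec.ld_decay, seed=None)
        _, ld, maf = simulate_haplotypes(config, rng)
        ids = np.array([f"rs{g}_{j}" for j in range(q)], dtype=object)
        ld = type(ld)(ids, ld.r)

        gene_entry = {"tss": int(tss), "chromosome": chrom, "strand": strand, "pairs": {}}
        for hyp in ("H3", "H4"):
            # a small effect draw can make the acceptance rule unreachable in
            # a small region; redraw the pair (fresh effects) a few times
            for _ in range(10):
                try:
                    pair = simulate_pair(hyp, density, tss, strand, positions, ld, maf,
                                         config, rng, chromosome=chrom)
                    break
                except SimulationError:
                    continue
            else:
                raise SimulationError(f"could not simulate an accepted {hyp} pair for {gene}")
            for tag, stats in (("t1", pair.stats1), ("t2", pair.stats2)):
                name = f"sumstats_{gene}_{hyp}_{tag}.tsv"
                write_sumstats(stats, outdir / name)
                manifest["files"][f"{gene}_{hyp}_{tag}"] = name
            gene_entry["pairs"][hyp] = {
                "causal1": pair.causal1,
                "causal2": pair.causal2,
                "causal1_id": str(ids[pair.causal1]),
                "causal2_id": str(ids[pair.causal2]),
                "gamma": [float(x) for x in pair.gamma],
                "attempts": list(pair.attempts_used),
            }
        ld_name = f"ld_{gene}.tsv"
        write_ld(ld, outdir / ld_name)
        manifest["files"][f"{gene}_ld"] = ld_name
        gene_entry["variant_ids"] = [str(v) for v in ids]
        gene_entry["positions"] = [int(p) for p in positions]
        manifest["genes"][gene] = gene_entry

        # ABC enhancers: intervals near the TSS, a few biosamples each
        for e in range(spec.abc_enhancers_per_gene):
            centre = int(tss + rng.integers(-spec.window // 2, spec.window // 2))
            start = max(centre - int(rng.integers(500, 3000)), 0)
            end = centre + int(rng.integers(500, 3000))
            for b in range(int(rng.integers(2, 5))):
                abc_rows.append(
                    {"chrom": chrom, "start": start, "end": end, "gene": gene,
                     "biosample": f"bio{b}", "score": round(float(rng.uniform(0.015, 0.5)), 6)}
                )

        # constraint scores tiling the region
        size = spec.gnocchi_region_size
        for start in range(tss - spec.window, tss + spec.window, size):
            if rng.random() < 0.7:  # deliberate gaps: nearest-region rule is exercised
                gnocchi_rows.append(
                    {"chrom": chrom, "start": start, "end": start + size,
                     "score": round(float(rng.normal(0.0, 1.5)), 4)}
                )

        # per-SNP variances for a fraction of variants
        covered = rng.random(q) < spec.polyfun_coverage
        for j in np.where(covered)[0]:
            polyfun_rows.append(
                {"chrom": chrom, "pos": int(positions[j]), "snp": str(ids[j]),
                 "variance": float(10.0 ** rng.uniform(-9, -6))}
            )

    if not polyfun_rows:  # keep the table readable even at zero coverage
        polyfun_rows.append({"chrom": "0", "pos": 1, "snp": "none", "variance": 1e-9})

    for name, rows in (("abc.tsv", abc_rows), ("gnocchi.tsv", gnocchi_rows),
                       ("polyfun.tsv", polyfun_rows)):
        pd.DataFrame(rows).to_csv(outdir / name, sep="\t", index=False, float_format="%.10g")
        manifest["files"][name.split(".")[0]] = name

    from .prior_sources import write_density

    write_density(density, outdir / "true_density.tsv", outdir / "true_density.json")
    manifest["files"]["true_density"] = "true_density.tsv"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
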