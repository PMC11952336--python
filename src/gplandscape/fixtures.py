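"""Synthetic data generators emulating the package's study designs.

Three kinds of fixture, each written as plain CSV/YAML files plus a truth
file for parameter-recovery checks:

* ``vc_landscape`` — a landscape drawn from a variance-component prior with
  geometrically decaying per-order variances, observed with Gaussian
  measurement noise (default variance 0.058, a typical replicate-pooled
  MAVE error), a small missing fraction, and a 0.1% held-out test split.
* ``seqdeft_counts`` — an epistatic sequence probability distribution
  (latent field drawn from the order-2 epistasis prior) sampled
  multinomially, emulating a genome-scale collection of a short regulatory
  element (a few thousand observations over a much larger sequence space).
* ``thermo_mave`` — log-signal measurements generated from the
  multi-register Shine-Dalgarno binding model with a strong consensus motif
  and realistic energy scales (allele effects well under the ~2 kcal/mol
  the strongest mismatches reach).

All randomness flows from a single integer seed; outputs are deterministic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gp import (DeltaPrior, VCPrior, sample_prior, simulate_counts,
                 simulate_observations)
from .space import SequenceSpace
from .thermo import RT, SDContext, ThermoParams, predict_log_gfp

__all__ = ["make_fixture", "default_vc_lambdas", "motif_thermo_params"]


def default_vc_lambdas(ell: int, total_variance: float = 1.0,
                       decay: float = 0.5) -> tuple:
    """Geometric per-order variances ``lambda_k prop decay^(k-1)``, k >= 1."""
    raw = np.array([0.0] + [decay ** (k - 1) for k in range(1, ell + 1)])
    raw[1:] *= total_variance / raw[1:].sum()
    return tuple(raw)


def motif_thermo_params(seed: int = 0, consensus: str = "AGGAGGAA",
                        depth: float = 0.46, beta0: float = 0.47,
                        sigma2: float = 0.01) -> ThermoParams:
    """Ground-truth binding parameters with a strong consensus motif.

    The consensus allele at each window position is stabilizing by ``depth``
    kcal/mol relative to the row mean (plus small seeded variation), giving
    the strongest binder a total advantage of about ``8 * depth`` and a
    realistic dynamic range of a few log units above background.
    """
    rng = np.random.default_rng(seed)
    alph = "ACGU"
    w = len(consensus)
    ddG = np.zeros((w, 4))
    for i, ch in enumerate(consensus):
        row = np.full(4, depth / 3)
        row[alph.index(ch)] = -depth
        row += 0.05 * rng.standard_normal(4)
        ddG[i] = row - row.mean()
    # theta0 such that an average sequence binds weakly relative to background
    theta0 = 3.0 * RT  # ~1.85 kcal/mol
    return ThermoParams(theta0=theta0, ddG=ddG, beta0=beta0, sigma2=sigma2)


def make_fixture(kind: str, outdir, seed: int = 0, **params) -> dict:
    """Generate one synthetic dataset; returns a manifest of written files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "vc_landscape":
        return _vc_landscape(outdir, seed, **params)
    if kind == "seqdeft_counts":
        return _seqdeft_counts(outdir, seed, **params)
    if kind == "thermo_mave":
        return _thermo_mave(outdir, seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _vc_landscape(outdir: Path, seed: int, ell: int = 5, alphabet: str = "ACGT",
                  lambdas=None, sigma2: float = 0.058,
                  missing_frac: float = 0.02,
                  test_frac: float = 0.001) -> dict:
    space = SequenceSpace([alphabet] * ell)
    if lambdas is None:
        lambdas = default_vc_lambdas(ell)
    rng = np.random.default_rng(seed)
    truth = sample_prior(space, VCPrior(lambdas), rng)
    obs = simulate_observations(truth, np.sqrt(sigma2), missing_frac, rng)

    n_test = max(1, int(round(obs.n_obs * test_frac)))
    test_pos = rng.choice(obs.n_obs, size=n_test, replace=False)
    is_test = np.zeros(obs.n_obs, dtype=bool)
    is_test[test_pos] = True

    seqs = space.genotype_strings(obs.obs_indices)
    frame = pd.DataFrame({"sequence": seqs, "y": obs.y, "var": obs.noise_var})
    frame[~is_test].to_csv(outdir / "train.csv", index=False)
    frame[is_test].to_csv(outdir / "test.csv", index=False)
    pd.DataFrame({"sequence": space.genotype_strings(),
                  "value": truth.values}).to_csv(outdir / "truth_landscape.csv",
                                                 index=False)
    meta = {"kind": "vc_landscape", "seed": seed, "ell": ell,
            "alphabet": alphabet, "lambdas": [float(x) for x in lambdas],
            "sigma2": sigma2, "missing_frac": missing_frac,
            "test_frac": test_frac}
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta))
    return {"train": outdir / "train.csv", "test": outdir / "test.csv",
            "truth": outdir / "truth_landscape.csv",
            "meta": outdir / "meta.yaml"}


def _seqdeft_counts(outdir: Path, seed: int, ell: int = 4,
                    alphabet: str = "ACGT", a_true: float = 500.0,
                    n_total: int = 5000) -> dict:
    space = SequenceSpace([alphabet] * ell)
    rng = np.random.default_rng(seed)
    phi = sample_prior(space, DeltaPrior(P=2, a=a_true), rng).values
    from scipy.special import softmax

    pi = softmax(-phi)
    data = simulate_counts(space, pi, n_total, rng)
    seqs = space.genotype_strings()
    pd.DataFrame({"sequence": seqs[data.counts > 0],
                  "count": data.counts[data.counts > 0]}
                 ).to_csv(outdir / "counts.csv", index=False)
    pd.DataFrame({"sequence": seqs, "pi": pi}
                 ).to_csv(outdir / "truth_pi.csv", index=False)
    meta = {"kind": "seqdeft_counts", "seed": seed, "ell": ell,
            "alphabet": alphabet, "a_true": a_true, "n_total": n_total}
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta))
    return {"counts": outdir / "counts.csv", "truth": outdir / "truth_pi.csv",
            "meta": outdir / "meta.yaml"}


def _thermo_mave(outdir: Path, seed: int, n: int = 5000,
                 sigma: float = 0.1) -> dict:
    rng = np.random.default_rng(seed)
    truth = motif_thermo_params(seed=seed, sigma2=0.0)
    context = SDContext()
    space = SequenceSpace(["ACGU"] * context.variable_length)
    idx = rng.choice(space.n_genotypes, size=n, replace=False)
    seqs = space.genotype_strings(idx)
    mu = predict_log_gfp(truth, seqs, context)
    y = mu + sigma * rng.standard_normal(n)
    pd.DataFrame({"sequence": seqs, "y": y, "var": sigma ** 2}
                 ).to_csv(outdir / "mave.csv", index=False)
    truth_rows = {"theta0": float(truth.theta0), "beta0": float(truth.beta0),
                  "sigma2": float(sigma ** 2),
                  "ddG": truth.ddG.tolist(),
                  "n_free_parameters": truth.n_free_parameters}
    (outdir / "truth_params.yaml").write_text(yaml.safe_dump(truth_rows))
    meta = {"kind": "thermo_mave", "seed": seed, "n": n, "sigma": sigma}
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta))
    return {"mave": outdir / "mave.csv",
            "truth": outdir / "truth_params.yaml",
            "meta": outdir / "meta.yaml"}
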