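"""End-to-end orchestration: screen → diversity → differentiation → mating.

``run_full_analysis`` executes the whole analysis on a dataset (read from
disk or simulated from a preset) and writes the three report tables the
analysis produces:

* ``diversity.tsv`` — per-population sample sizes, error-screen flags,
  observed/expected heterozygosity and mean allele counts;
* ``differentiation.tsv`` + ``ibd.tsv`` — per-locus and multilocus F_st
  with chi-square p-values, the isolation-by-distance regression and the
  altitude correlation;
* ``mating.tsv`` — the mating-system parameter set per population, each
  entry formatted "estimate (SE)".

Every table carries a header comment recording the package version, seed
and options, and a JSON bundle aggregates the numbers for programmatic
use.  Reports are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .error_screen import screen_dataset
from .genodata import StudyDataset, read_progeny_dataset
from .mating_model import EMOptions, fit_with_bootstrap
from .popstruct import (
    allele_frequencies,
    altitude_correlation,
    altitude_difference_matrix,
    differentiation,
    distance_matrix,
    heterozygosities,
    ibd_regression,
    pairwise_fst,
)
from .simulate import generate_study_like_dataset


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One input source (path or preset), options, seed, output directory."""

    output_dir: str | Path = "results"
    input_path: str | Path | None = None
    input_format: str = "tsv"
    simulate_preset: str | None = None  # "study-like"
    seed: int = 0
    alpha: float = 0.05
    screen_reps: int = 1000
    bootstrap: int = 1000
    mantel_reps: int = 999
    em: EMOptions = field(default_factory=EMOptions)

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate_preset is None):
            raise ConfigError("exactly one of input_path / simulate_preset required")
        if self.simulate_preset not in (None, "study-like"):
            raise ConfigError(f"unknown preset {self.simulate_preset!r}")


def _fmt(est: float, se: float | None) -> str:
    if est is None or (isinstance(est, float) and math.isnan(est)):
        return "NA"
    if se is None or (isinstance(se, float) and math.isnan(se)):
        return f"{est:.3f}"
    return f"{est:.3f} ({se:.3f})"


def _header(config: PipelineConfig) -> str:
    return (
        f"# matearray {__version__} | seed={config.seed} "
        f"| alpha={config.alpha} | bootstrap={config.bootstrap}\n"
    )


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run screen → diversity → F_st/IBD → mating fits; write all reports.

    Returns the JSON-serializable result bundle.  Any stage failure
    leaves the reports written so far in place and re-raises.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate_preset:
        dataset, _truth = generate_study_like_dataset(config.seed)
    else:
        dataset = read_progeny_dataset(config.input_path, config.input_format)

    bundle: dict = {
        "version": __version__,
        "seed": config.seed,
        "options": {"alpha": config.alpha, "bootstrap": config.bootstrap},
    }

    # 1. genotyping-error screen (pooled families per population)
    screen = screen_dataset(
        dataset, alpha=config.alpha, n_reps=config.screen_reps, seed=config.seed
    )
    null_by_pop: dict[str, dict[str, float]] = {}
    for res in screen:
        if res.null_allele_flag:
            null_by_pop.setdefault(res.population, {})[res.locus] = (
                res.null_frequency_estimate
            )
    bundle["screen"] = [
        {
            "population": r.population, "locus": r.locus,
            "null": r.null_allele_flag, "stutter": r.stutter_flag,
            "dropout": r.dropout_flag,
            "null_frequency": r.null_frequency_estimate,
        }
        for r in screen
    ]

    # 2. allele frequencies + diversity (null frequencies folded in)
    null_estimates = {
        (pop, locus): nu
        for pop, m in null_by_pop.items() for locus, nu in m.items()
    }
    freqs = allele_frequencies(dataset, null_estimates)
    div = heterozygosities(dataset, freqs)
    rows = []
    for pop in dataset.populations:
        s = div.summary[div.summary.population == pop.name].iloc[0]
        flags = [r for r in screen if r.population == pop.name]
        rows.append(
            {
                "population": pop.name,
                "latitude": pop.latitude, "longitude": pop.longitude,
                "altitude": pop.altitude,
                "n_families": len(pop.families),
                "n_seeds": pop.n_offspring,
                "stutter_loci": ",".join(r.locus for r in flags if r.stutter_flag)
                or "No",
                "dropout_loci": ",".join(r.locus for r in flags if r.dropout_flag)
                or "No",
                "null_loci": ",".join(r.locus for r in flags if r.null_allele_flag)
                or "No",
                "Ho": f"{s.Ho_mean:.3f} ± {s.Ho_sd:.3f}",
                "He": f"{s.He_mean:.3f} ± {s.He_sd:.3f}",
                "mean_alleles": f"{s.alleles_mean:.3f} ± {s.alleles_sd:.3f}",
            }
        )
    table2 = pd.DataFrame(rows)
    with open(outdir / "diversity.tsv", "w") as fh:
        fh.write(_header(config))
        table2.to_csv(fh, sep="\t", index=False)
    bundle["diversity"] = table2.to_dict(orient="records")

    # 3. differentiation, pairwise F_st, IBD, altitude correlation
    diff = differentiation(freqs)
    pw = pairwise_fst(freqs)
    dmat = distance_matrix(dataset)
    amat = altitude_difference_matrix(dataset)
    ibd = ibd_regression(pw, dmat, method="mantel",
                         mantel_reps=config.mantel_reps, seed=config.seed)
    alt_r, alt_p = altitude_correlation(pw, amat)
    rows = []
    for locus, fst in diff.fst_by_locus.items():
        chi2, dfree, p = diff.chi2_by_locus[locus]
        rows.append({"locus": locus, "Fst": fst, "chi2": chi2, "df": dfree,
                     "p_value": p})
    rows.append({"locus": "Over loci", "Fst": diff.fst_multilocus,
                 "chi2": math.nan, "df": math.nan, "p_value": math.nan})
    table3 = pd.DataFrame(rows)
    with open(outdir / "differentiation.tsv", "w") as fh:
        fh.write(_header(config))
        table3.to_csv(fh, sep="\t", index=False)
    ibd_row = pd.DataFrame(
        [{"a": ibd.a, "p_a": ibd.p_a, "b": ibd.b, "p_b": ibd.p_b,
          "r_squared": ibd.r_squared, "mantel_p": ibd.mantel_p,
          "n_pairs": ibd.n_pairs,
          "altitude_r": alt_r, "altitude_p": alt_p}]
    )
    with open(outdir / "ibd.tsv", "w") as fh:
        fh.write(_header(config))
        ibd_row.to_csv(fh, sep="\t", index=False)
    bundle["differentiation"] = table3.to_dict(orient="records")
    bundle["ibd"] = ibd_row.to_dict(orient="records")[0]
    bundle["pairwise_fst"] = {
        f"{a}|{b}": float(pw.loc[a, b])
        for i, a in enumerate(pw.index) for b in pw.index[i + 1:]
    }

    # 4. mating-system fits per population
    param_order = ["t_m", "alpha_m", "t_s", "alpha_s", "tm_minus_ts", "F",
                   "r_s", "r_p_m", "r_p_s", "rps_minus_rpm", "r_loci"]
    mating: dict[str, dict] = {}
    for pop in dataset.populations:
        est = fit_with_bootstrap(
            dataset, pop.name, B=config.bootstrap, seed=config.seed,
            screen=null_by_pop.get(pop.name, {}), options=config.em,
        )
        mating[pop.name] = {
            "point": est.point.as_dict(), "se": est.se,
            "converged": est.converged, "loglik": est.loglik,
            "n_bootstrap_failed": est.n_bootstrap_failed,
        }
    table4 = pd.DataFrame(
        {
            pop: {
                par: _fmt(vals["point"].get(par), vals["se"].get(par))
                for par in param_order
            }
            for pop, vals in mating.items()
        }
    )
    table4.index.name = "parameter"
    with open(outdir / "mating.tsv", "w") as fh:
        fh.write(_header(config))
        table4.to_csv(fh, sep="\t")
    bundle["mating"] = mating

    with open(outdir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    return bundle
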