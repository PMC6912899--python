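"""End-to-end orchestration: simulate -> summarize -> model choice ->
parameter estimation -> POD validation, with reproducible manifests.

The configuration is a flat ``key = value`` text file (or a dict); every
result table carries the configuration hash and master seed so deleting
intermediates and re-running reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abcrf import (
    ParamEstimator,
    append_lda,
    build_reference,
    prior_range_check,
    replicate_model_choice,
)
from .coalsim import MarkerConfig, ScenarioSpec, default_prior, sample_prior, simulate_joint
from .io import read_fasta_with_map, read_genepop
from .sumstats import summarize_pair
from .synth import make_pods


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "mitosat_out"
    scenarios: tuple[int, ...] = (1, 2, 3, 4)
    n_per_scenario: int = 5000
    subsample: int = 20000
    n_rep: int = 10
    n_trees: int = 500
    n_estimation: int = 20000
    n_pods: int = 200
    n_sat_loci: int = 25
    seq_length: int = 2516
    n_diploid: tuple[int, int] = (126, 44)
    n_haploid: tuple[int, int] = (38, 23)
    observed_genepop: str | None = None
    observed_fasta: str | None = None
    observed_map: str | None = None
    observed_scenario: int = 3

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` configuration file; unknown keys
        raise a validation error naming the key."""
        known = set(cls.__dataclass_fields__)
        kwargs: dict = {}
        for line_no, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {line_no}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"unknown configuration key {key!r}")
            f = cls.__dataclass_fields__[key]
            if f.type in ("int", int):
                kwargs[key] = int(value)
            elif key in ("scenarios", "n_diploid", "n_haploid"):
                kwargs[key] = tuple(int(v) for v in value.replace(",", " ").split())
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def marker_config(self) -> MarkerConfig:
        return MarkerConfig(
            n_sat_loci=self.n_sat_loci,
            seq_length=self.seq_length,
            n_diploid=tuple(self.n_diploid),
            n_haploid=tuple(self.n_haploid),
        )


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full inference chain and write all result tables.

    Returns a bundle with the observed statistics, the model-choice result,
    the parameter estimates and the POD-validation table. Any stage failure
    raises :class:`StageError` naming the stage; partial outputs stay on
    disk next to a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed, "version": __version__}
    rng = np.random.default_rng(config.seed)
    prior = default_prior()
    mconfig = config.marker_config()
    stage = "setup"
    bundle: dict = {}
    try:
        stage = "observed"
        if config.observed_genepop:
            table = read_genepop(config.observed_genepop)
            alignment = read_fasta_with_map(config.observed_fasta, config.observed_map)
            observed_truth = None
        else:
            pod_rng = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
            params = sample_prior(prior, pod_rng)
            table, alignment = simulate_joint(
                ScenarioSpec(config.observed_scenario), params, mconfig, pod_rng
            )
            observed_truth = params.as_dict()
        observed = summarize_pair(table, alignment)
        bundle["observed_stats"] = observed
        bundle["observed_truth"] = observed_truth

        stage = "reference"
        reference = build_reference(
            prior, list(config.scenarios), config.n_per_scenario, mconfig, rng
        )
        check = prior_range_check(reference, observed.values)
        _write_tsv(check, out / "prior_check.tsv", meta)
        _write_tsv(reference.df, out / "reference.tsv", meta)

        stage = "model_choice"
        ref_aug, obs_aug = append_lda(reference, observed.values)
        subsample = min(config.subsample, len(ref_aug.df))
        choice = replicate_model_choice(
            ref_aug, obs_aug, n_rep=config.n_rep, subsample=subsample,
            n_trees=config.n_trees, rng=rng,
        )
        votes = pd.DataFrame(
            {
                "votes_pct": choice.votes,
                "votes_se": choice.votes_se,
            }
        )
        votes["selected"] = [s == choice.selected for s in votes.index]
        votes["posterior_probability"] = np.where(
            votes["selected"], choice.posterior_probability, np.nan
        )
        votes["prior_error_rate"] = np.where(
            votes["selected"], choice.prior_error_rate, np.nan
        )
        _write_tsv(votes, out / "votes.tsv", meta)
        bundle["model_choice"] = choice

        stage = "estimation"
        best = ScenarioSpec(choice.selected)
        est_ref = build_reference(
            prior, [best.scenario_id], config.n_estimation, mconfig, rng
        )
        estimator = ParamEstimator(n_trees=config.n_trees).fit(est_ref, rng=rng)
        estimate = estimator.estimate(observed.values)
        _write_tsv(estimate.estimates, out / "estimates.tsv", meta)
        bundle["estimate"] = estimate

        stage = "pod_validation"
        if config.n_pods > 0:
            pods = make_pods(prior, best, config.n_pods, mconfig, rng)
            stats = np.stack([summarize_pair(t, a).values for t, a, _ in pods])
            truth = pd.DataFrame([tr.params for _, _, tr in pods])
            from .abcrf import validate_pods

            validation = validate_pods(estimator, stats, truth)
            _write_tsv(validation, out / "validation.tsv", meta)
            bundle["validation"] = validation

        stage = "manifest"
        manifest = dict(
            meta,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            stages=["observed", "reference", "model_choice", "estimation", "pod_validation"],
            config=asdict(config),
            selected_scenario=choice.selected,
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
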