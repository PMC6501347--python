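"""Command-line interface, run configuration and end-to-end recipes.

Ties the pipeline together: dataset construction (decoys + reversal
augmentation + descriptors + exact spectra), full-dataset training,
cross-validation, the non-informative baseline and the prune-and-predict
experiment.  One YAML configuration file drives all stages; every stochastic
stage takes an explicit seed and re-runs with an unchanged configuration
reuse cached datasets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chainio, descriptor, evalcv, pruning, surrogate
from .betagm import ENMParams, betagm_spectrum
from .chainio import ChainStructure
from .descriptor import coulomb_matrix
from .surrogate import SurrogateConfig

logger = logging.getLogger(__name__)

RECIPES = ("build_dataset", "train_full", "cross_validate", "baseline", "prune_predict")


@dataclass
class Dataset:
    """In-memory dataset: chains, descriptors, exact spectra, manifest."""

    chains: list[ChainStructure]
    x: np.ndarray  # (S, N, N) descriptors
    y: np.ndarray  # (S, 10) exact eigenvalues
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.chains)


def build_dataset(
    chains: Sequence[ChainStructure],
    window: int = 100,
    params: ENMParams | None = None,
    *,
    augment_reversal: bool = True,
    n_modes: int = 10,
    skip_unsound: bool = False,
) -> Dataset:
    """Decoys from each chain, optional reversal doubling, descriptors, spectra.

    Spectra are computed once per direct decoy and shared with the reversed
    copy (the model spectrum is orientation-invariant); descriptors are
    computed per orientation since the matrix is order-dependent.
    ``skip_unsound`` drops decoys whose network has internal mechanisms
    (zero-mode count other than six) instead of keeping them.
    """
    import warnings as _warnings

    params = params or ENMParams()
    samples: list[ChainStructure] = []
    targets: list[np.ndarray] = []
    for chain in chains:
        for decoy in chainio.make_decoys(chain, window):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                spec = betagm_spectrum(decoy, params, n_modes)
            if skip_unsound and spec.zero_mode_count != 6:
                logger.warning(
                    "dropping mechanically unsound decoy %s@%s (%d zero modes)",
                    decoy.source_id, decoy.window_offset, spec.zero_mode_count,
                )
                continue
            samples.append(decoy)
            targets.append(spec.eigenvalues)
            if augment_reversal:
                samples.append(chainio.reverse_chain(decoy))
                targets.append(spec.eigenvalues)
    x = np.stack([coulomb_matrix(c).matrix for c in samples])
    y = np.stack(targets)
    return Dataset(
        chains=samples, x=x, y=y, manifest=chainio.manifest_frame(samples)
    )


def synthetic_sources(
    count: int,
    length_range: tuple[int, int] = (105, 110),
    compactness_range: tuple[float, float] = (0.1, 0.9),
    gly_fraction: float = 0.08,
    seed: int = 0,
) -> list[ChainStructure]:
    """Generate a diverse pool of parent chains for decoy construction."""
    rng = np.random.default_rng(seed)
    chains = []
    for i in range(count):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        compactness = float(rng.uniform(*compactness_range))
        chains.append(
            chainio.generate_synthetic_chain(
                n,
                compactness,
                gly_fraction,
                seed=int(rng.integers(2**31)),
                source_id=f"synth{i:04d}",
            )
        )
    return chains


def save_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mats = [
        descriptor.CoulombMatrix(
            matrix=m,
            source_id=c.source_id,
            window_offset=c.window_offset,
            orientation=c.orientation,
        )
        for m, c in zip(dataset.x, dataset.chains)
    ]
    descriptor.write_descriptor_set(out / "dataset.h5", mats, dataset.y)
    dataset.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def load_dataset(data_dir: str | Path) -> Dataset:
    data_dir = Path(data_dir)
    x, y, meta = descriptor.read_descriptor_set(data_dir / "dataset.h5")
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    chains: list[ChainStructure] = []  # coordinates are not round-tripped
    return Dataset(chains=chains, x=x, y=y, manifest=manifest)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration shared by all recipes."""

    data_dir: str = "data"
    model_dir: str = "models"
    report_dir: str = "reports"
    window: int = 100
    n_sources: int = 50
    length_range: tuple[int, int] = (105, 110)
    compactness_range: tuple[float, float] = (0.1, 0.9)
    gly_fraction: float = 0.08
    dataset_seed: int = 0
    enm: ENMParams = field(default_factory=ENMParams)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    cv_folds: int = 5
    cv_repeats: int = 10
    train_seeds: tuple[int, ...] = tuple(range(10))
    pruning: pruning.PruningScheme = field(default_factory=pruning.PruningScheme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "enm" in kwargs:
            kwargs["enm"] = ENMParams(**kwargs["enm"])
        if "surrogate" in kwargs:
            kwargs["surrogate"] = SurrogateConfig(**kwargs["surrogate"])
        if "pruning" in kwargs:
            kwargs["pruning"] = pruning.PruningScheme(**kwargs["pruning"])
        for key in ("length_range", "compactness_range", "train_seeds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log_provenance(config: RunConfig, out_dir: Path, stage: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    info = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / f"{stage}.provenance.json").write_text(
        json.dumps(info, indent=2, default=str)
    )


def run_pipeline(config: RunConfig, recipe: str) -> dict:
    """Execute one named recipe; returns a dict of produced artifacts."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; valid recipes: {RECIPES}")
    data_dir = Path(config.data_dir)
    model_dir = Path(config.model_dir)
    report_dir = Path(config.report_dir)

    if recipe == "build_dataset":
        marker = data_dir / "dataset.hash"
        if (
            marker.exists()
            and marker.read_text() == config.config_hash()
            and (data_dir / "dataset.h5").exists()
        ):
            logger.info("dataset up to date, reusing cache")
            return {"dataset": str(data_dir / "dataset.h5"), "cached": True}
        sources = synthetic_sources(
            config.n_sources,
            config.length_range,
            config.compactness_range,
            config.gly_fraction,
            config.dataset_seed,
        )
        dataset = build_dataset(sources, config.window, config.enm)
        save_dataset(dataset, data_dir)
        _log_provenance(config, data_dir, "build_dataset")
        marker.write_text(config.config_hash())
        return {"dataset": str(data_dir / "dataset.h5"), "n_samples": len(dataset)}

    if recipe == "train_full":
        dataset = load_dataset(data_dir)
        paths = []
        for seed in config.train_seeds:
            cfg = dataclasses.replace(config.surrogate, seed=seed)
            model = surrogate.build_model(cfg)
            trained = surrogate.train(model, dataset.x, dataset.y, config=cfg)
            out = model_dir / f"seed{seed}"
            surrogate.save_surrogate(trained, out)
            paths.append(str(out))
        _log_provenance(config, model_dir, "train_full")
        return {"models": paths}

    if recipe == "cross_validate":
        dataset = load_dataset(data_dir)
        report = evalcv.cross_validate(
            dataset.x,
            dataset.y,
            dataset.manifest,
            config.surrogate,
            k=config.cv_folds,
            repeats=config.cv_repeats,
            seeds=config.train_seeds[: config.cv_repeats],
        )
        report_dir.mkdir(parents=True, exist_ok=True)
        out = report_dir / "cv_report.tsv"
        report.to_frame().to_csv(out, sep="\t", index=False)
        _log_provenance(config, report_dir, "cross_validate")
        return {"report": str(out), "overall_mape": report.overall_mape}

    if recipe == "baseline":
        dataset = load_dataset(data_dir)
        pred = evalcv.baseline_predict(dataset.y, len(dataset.y))
        report = evalcv.evaluate(dataset.y, pred, context="baseline")
        report_dir.mkdir(parents=True, exist_ok=True)
        out = report_dir / "baseline_report.tsv"
        report.to_frame().to_csv(out, sep="\t", index=False)
        _log_provenance(config, report_dir, "baseline")
        return {"report": str(out), "overall_mape": report.overall_mape}

    # prune_predict
    models = [
        surrogate.load_surrogate(p) for p in sorted(model_dir.glob("seed*"))
    ]
    if not models:
        raise FileNotFoundError(f"no trained models under {model_dir}")
    chain = chainio.generate_dumbbell_chain(seed=config.dataset_seed)
    report = pruning.pruning_experiment(chain, models, config.pruning, config.enm)
    report_dir.mkdir(parents=True, exist_ok=True)
    out = report_dir / f"prune_{config.pruning.kind}.tsv"
    pd.DataFrame(
        {
            "eigenvalue": np.arange(1, len(report.true_eigenvalues) + 1),
            "true": report.true_eigenvalues,
            "mean_predicted": report.mean_predicted,
            "std_predicted": report.std_predicted,
        }
    ).to_csv(out, sep="\t", index=False)
    _log_provenance(config, report_dir, "prune_predict")
    return {"report": str(out), "overall_mape": report.overall_mape}


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def main(argv: Sequence[str] | None = None) -> None:
    cli(args=argv)


try:
    import click
except ImportError:  # pragma: no cover - click is a hard dependency
    click = None


if click is not None:

    @click.group(name="enmspec")
    @click.option("-v", "--verbose", is_flag=True, help="Enable debug logging.")
    def cli(verbose: bool) -> None:
        """Elastic-network spectra and their convolutional surrogate."""
        logging.basicConfig(
            level=logging.DEBUG if verbose else logging.INFO,
            stream=sys.stderr,
            format="%(levelname)s %(name)s: %(message)s",
        )

    @cli.command()
    @click.option("--pdb", "pdb_path", required=True, type=click.Path(exists=True))
    @click.option("--chain", "chain_id", default=None)
    @click.option("--window", default=100, show_default=True)
    @click.option("--out", "out_dir", required=True, type=click.Path())
    def decoys(pdb_path, chain_id, window, out_dir):
        """Cut fixed-length decoys from a PDB chain."""
        chain = chainio.read_calpha_trace(Path(pdb_path).read_text(), chain_id)
        items = chainio.make_decoys(chain, window)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for d in items:
            chainio.write_chain_table(d, out / f"{d.source_id}_w{d.window_offset}.tsv")
        chainio.write_manifest(items, out / "manifest.tsv")
        click.echo(f"wrote {len(items)} decoys to {out}")

    @cli.command()
    @click.option("--n", default=100, show_default=True)
    @click.option("--count", default=1, show_default=True)
    @click.option("--compactness", default=0.7, show_default=True)
    @click.option("--gly-fraction", default=0.08, show_default=True)
    @click.option("--seed", default=0, show_default=True)
    @click.option("--out", "out_dir", required=True, type=click.Path())
    def synth(n, count, compactness, gly_fraction, seed, out_dir):
        """Generate synthetic protein-like chains."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(seed)
        chains = []
        for i in range(count):
            c = chainio.generate_synthetic_chain(
                n, compactness, gly_fraction, seed=int(rng.integers(2**31)),
                source_id=f"synth{i:04d}",
            )
            chainio.write_chain_table(c, out / f"{c.source_id}.tsv")
            chains.append(c)
        chainio.write_manifest(chains, out / "manifest.tsv")
        click.echo(f"wrote {count} chains to {out}")

    @cli.command()
    @click.option("--pdb", "pdb_path", required=True, type=click.Path(exists=True))
    @click.option("--chain", "chain_id", default=None)
    @click.option("--model", "model_kind", default="beta_gm", show_default=True,
                  type=click.Choice(["beta_gm", "anm_calpha"]))
    @click.option("--cutoff", default=7.5, show_default=True)
    @click.option("--out", "out_path", required=True, type=click.Path())
    def spectrum(pdb_path, chain_id, model_kind, cutoff, out_path):
        """Exact low spectrum of one chain (TSV row)."""
        chain = chainio.read_calpha_trace(Path(pdb_path).read_text(), chain_id)
        params = ENMParams(cutoff=cutoff, model=model_kind)
        spec = betagm_spectrum(chain, params)
        row = {"source_id": chain.source_id, "zero_mode_count": spec.zero_mode_count}
        row.update({f"lambda{i+1}": v for i, v in enumerate(spec.eigenvalues)})
        pd.DataFrame([row]).to_csv(out_path, sep="\t", index=False)
        click.echo(f"wrote spectrum to {out_path}")

    def _load_config(config_path) -> RunConfig:
        return RunConfig.from_yaml(config_path) if config_path else RunConfig()

    @cli.command()
    @click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
    @click.option("--config", "config_path", default=None, type=click.Path(exists=True))
    @click.option("--seed", default=0, show_default=True)
    @click.option("--out", "out_dir", required=True, type=click.Path())
    def train(data_dir, config_path, seed, out_dir):
        """Train one surrogate on a prepared dataset directory."""
        cfg = _load_config(config_path)
        cfg.data_dir = data_dir
        cfg.model_dir = out_dir
        cfg.train_seeds = (seed,)
        result = run_pipeline(cfg, "train_full")
        click.echo(json.dumps(result))

    @cli.command()
    @click.option("--model", "model_dir", required=True, type=click.Path(exists=True))
    @click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
    @click.option("--out", "out_path", required=True, type=click.Path())
    def predict(model_dir, data_dir, out_path):
        """Predict eigenvalues for every sample of a dataset."""
        trained = surrogate.load_surrogate(model_dir)
        dataset = load_dataset(data_dir)
        preds = surrogate.predict(trained, dataset.x)
        frame = pd.DataFrame(
            preds, columns=[f"lambda{i+1}" for i in range(preds.shape[1])]
        )
        frame.insert(0, "sample", np.arange(len(frame)))
        frame.to_csv(out_path, sep="\t", index=False)
        click.echo(f"wrote predictions to {out_path}")

    @cli.command()
    @click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
    @click.option("--config", "config_path", default=None, type=click.Path(exists=True))
    @click.option("--k", default=5, show_default=True)
    @click.option("--repeats", default=10, show_default=True)
    @click.option("--out", "out_path", required=True, type=click.Path())
    def cv(data_dir, config_path, k, repeats, out_path):
        """Repeated k-fold cross-validation."""
        cfg = _load_config(config_path)
        cfg.data_dir = data_dir
        cfg.cv_folds = k
        cfg.cv_repeats = repeats
        cfg.report_dir = str(Path(out_path).parent)
        dataset = load_dataset(data_dir)
        report = evalcv.cross_validate(
            dataset.x, dataset.y, dataset.manifest, cfg.surrogate,
            k=k, repeats=repeats,
        )
        report.to_frame().to_csv(out_path, sep="\t", index=False)
        click.echo(f"overall MAPE {report.overall_mape:.2f}")

    @cli.command()
    @click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
    @click.option("--out", "out_path", required=True, type=click.Path())
    def baseline(data_dir, out_path):
        """Non-informative mean-predictor baseline on a dataset."""
        dataset = load_dataset(data_dir)
        pred = evalcv.baseline_predict(dataset.y, len(dataset.y))
        report = evalcv.evaluate(dataset.y, pred, context="baseline")
        report.to_frame().to_csv(out_path, sep="\t", index=False)
        click.echo(f"baseline MAPE {report.overall_mape:.2f}")

    @cli.command(name="prune-predict")
    @click.option("--pdb", "pdb_path", required=True, type=click.Path(exists=True))
    @click.option("--chain", "chain_id", default=None)
    @click.option("--models", "model_dir", required=True, type=click.Path(exists=True))
    @click.option("--scheme", default="random", show_default=True,
                  type=click.Choice(list(pruning.SCHEME_KINDS)))
    @click.option("--n-remove", default=20, show_default=True)
    @click.option("--radius", default=10.0, show_default=True)
    @click.option("--n-structures", default=100, show_default=True)
    @click.option("--seed", default=0, show_default=True)
    @click.option("--out", "out_path", required=True, type=click.Path())
    def prune_predict(pdb_path, chain_id, model_dir, scheme, n_remove, radius,
                      n_structures, seed, out_path):
        """Prune a longer chain and score ensemble predictions."""
        chain = chainio.read_calpha_trace(Path(pdb_path).read_text(), chain_id)
        models = [
            surrogate.load_surrogate(p) for p in sorted(Path(model_dir).glob("seed*"))
        ]
        if not models:
            raise click.ClickException(f"no trained models under {model_dir}")
        scheme_obj = pruning.PruningScheme(
            kind=scheme, n_remove=n_remove, sphere_radius=radius,
            n_structures=n_structures, seed=seed,
        )
        report = pruning.pruning_experiment(chain, models, scheme_obj)
        pd.DataFrame(
            {
                "eigenvalue": np.arange(1, len(report.true_eigenvalues) + 1),
                "true": report.true_eigenvalues,
                "mean_predicted": report.mean_predicted,
                "std_predicted": report.std_predicted,
            }
        ).to_csv(out_path, sep="\t", index=False)
        click.echo(f"{scheme} MAPE {report.overall_mape:.2f}")

    @cli.command()
    @click.option("--config", "config_path", default=None, type=click.Path(exists=True))
    @click.argument("recipe", type=click.Choice(list(RECIPES)))
    def pipeline(config_path, recipe):
        """Run one end-to-end recipe."""
        cfg = _load_config(config_path)
        result = run_pipeline(cfg, recipe)
        click.echo(json.dumps(result, default=str))
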