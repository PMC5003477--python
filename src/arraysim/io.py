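"""File I/O: seed-level input, TSV matrix/truth output, run configuration.

The canonical on-disk format is TSV with gene rows and sample columns
(``cont1..cont{m1}``, ``test1..test{m2}``), numbers written at full
precision so a write/read round trip reproduces the matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams, SimulatedDataset, draw_base_levels

__all__ = [
    "RunConfig",
    "read_seed_levels",
    "write_dataset",
    "read_expression",
    "make_fixture_seed",
    "CONFIG_KEYS",
]

# Config-file / CLI spellings of the model parameters.
CONFIG_KEYS = {
    "n": "n",
    "m1": "m1",
    "m2": "m2",
    "ratio": "ratio",
    "shape2": "shape2",
    "lb": "lb",
    "ub": "ub",
    "pde": "pde",
    "sym": "sym",
    "lambda1": "lambda1",
    "lambda2": "lambda2",
    "muminde": "mu_de_min",
    "sdde": "sd_de",
    "sdn": "sd_n",
    "rseed": "rseed",
}
_FIELD_TO_KEY = {v: k for k, v in CONFIG_KEYS.items()}

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def read_seed_levels(path) -> np.ndarray:
    """Read per-gene log2 mean levels from a plain-text/TSV file.

    Uses the first column; a single non-numeric first line is treated as a
    header.  Raises ``FileNotFoundError``, or ``ValueError`` naming the
    offending line for empty or malformed files.
    """
    path = Path(path)
    text = path.read_text()
    values = []
    first_data_line = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        token = line.replace(",", "\t").split("\t")[0].split()[0]
        try:
            values.append(float(token))
        except ValueError:
            if first_data_line:  # optional header
                first_data_line = False
                continue
            raise ValueError(
                f"{path}: line {lineno} is not numeric: {token!r}"
            ) from None
        first_data_line = False
    if not values:
        raise ValueError(f"{path}: no numeric seed levels found")
    return np.asarray(values, dtype=float)


def write_dataset(
    dataset: SimulatedDataset, out_dir, emit_noise_free: bool = False
) -> dict[str, Path]:
    """Write the expression matrix, the DE truth table and optionally the
    noise-free matrix as TSV under ``out_dir``; returns the paths written.

    Expression columns are named ``cont1..cont{m1}, test1..test{m2}``; the
    truth file has columns ``gene_index`` (0-based) and ``de_status``
    (-1/0/1).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = dataset.params
    columns = [f"cont{j + 1}" for j in range(p.m1)] + [
        f"test{j + 1}" for j in range(p.m2)
    ]
    paths: dict[str, Path] = {}

    expr = out_dir / "expression.tsv"
    _write_matrix(expr, dataset.x, columns)
    paths["expression"] = expr

    truth = out_dir / "de_truth.tsv"
    pd.DataFrame(
        {"gene_index": np.arange(p.n), "de_status": dataset.de_status}
    ).to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth

    if emit_noise_free:
        nf = out_dir / "noise_free.tsv"
        _write_matrix(nf, dataset.y_noise_free, ["reference"] + columns)
        paths["noise_free"] = nf
    return paths


def _write_matrix(path: Path, x: np.ndarray, columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        np.savetxt(fh, x, fmt=_FLOAT_FMT, delimiter="\t")


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV written by :func:`write_dataset` back into a
    DataFrame with the original column names.

    Uses exact float parsing so a write/read round trip is bit-identical.
    """
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def make_fixture_seed(n: int, rng: np.random.Generator, path) -> Path:
    """Write a synthetic seed-level file of ``n`` per-gene log2 means drawn
    from the model's own beta/scaling step, so seed-data code paths can be
    exercised without any real dataset."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    levels = draw_base_levels(ModelParams(n=n), rng)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("meanlog2\n")
        np.savetxt(fh, levels.zbar, fmt=_FLOAT_FMT)
    return path


@dataclass(frozen=True)
class StudyConfig:
    n_replicates: int = 100
    p_threshold: float = 0.006
    base_seed: int | None = None


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration: model parameters, study settings, output
    location and logging; round-trips exactly through YAML."""

    model: ModelParams = field(default_factory=ModelParams)
    study: StudyConfig = field(default_factory=StudyConfig)
    output_dir: str = "."
    emit_noise_free: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        model = {
            _FIELD_TO_KEY[f]: getattr(self.model, f)
            for f in _FIELD_TO_KEY
        }
        return {
            "model": model,
            "study": {
                "replicates": self.study.n_replicates,
                "p_threshold": self.study.p_threshold,
                "base_seed": self.study.base_seed,
            },
            "output_dir": self.output_dir,
            "emit_noise_free": self.emit_noise_free,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        model_kwargs = {
            CONFIG_KEYS[k]: v for k, v in d.get("model", {}).items()
        }
        study = d.get("study", {})
        return cls(
            model=ModelParams(**model_kwargs),
            study=StudyConfig(
                n_replicates=study.get("replicates", 100),
                p_threshold=study.get("p_threshold", 0.006),
                base_seed=study.get("base_seed"),
            ),
            output_dir=d.get("output_dir", "."),
            emit_noise_free=d.get("emit_noise_free", False),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
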