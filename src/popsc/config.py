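"""Run configuration: every numeric threshold the pipeline applies, in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

CONTROL = "control"
POP = "POP"
CONDITIONS = (CONTROL, POP)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes used by the analysis stages.

    Defaults follow the study design this pipeline reproduces: cells are kept
    when they detect between ``min_genes`` and ``max_genes`` genes (inclusive)
    with a mitochondrial count fraction strictly below ``max_mito_frac``;
    expression is library-size normalized to ``norm_size_factor`` molecules per
    cell and log-transformed; pseudobulk replicates sum ``pseudobulk_group_size``
    cells; differential expression calls |log2FC| > ``de_abs_log2fc`` at
    p < ``de_alpha``; ligand-receptor pairs are filtered at
    ``lr_min_expr_frac`` expressing cells and called at p < ``lr_alpha`` from
    ``n_permutations`` label permutations; proportion shifts are called at
    |log2FC| > ``prop_abs_log2fc``.
    """

    min_genes: int = 500
    max_genes: int = 3500
    max_mito_frac: float = 0.10
    norm_size_factor: float = 10_000.0
    n_hvg: int = 2000
    pseudobulk_group_size: int = 20
    de_abs_log2fc: float = 0.5
    de_alpha: float = 0.05
    lr_min_expr_frac: float = 0.10
    lr_alpha: float = 0.01
    n_permutations: int = 1000
    prop_abs_log2fc: float = 0.5
    rng_seed: int = 0
    # secondary knobs (toolchain defaults, overridable)
    marker_min_pct: float = 0.10
    marker_min_abs_log2fc: float = 0.25
    marker_alpha: float = 0.05
    min_cells_per_cluster: int = 3
    pseudobulk_min_remainder: int = 10
    min_cells_per_stratum: int = 10
    dispersion_prior_reps: float = 10.0
    use_tmm_offsets: bool = False
    enrich_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        for name in ("min_genes", "max_genes", "max_mito_frac", "norm_size_factor",
                     "n_hvg", "pseudobulk_group_size", "de_abs_log2fc",
                     "lr_min_expr_frac", "n_permutations", "prop_abs_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("de_alpha", "lr_alpha", "marker_alpha", "enrich_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a plain-text config file.

    Accepts either JSON or ``key = value`` lines (``#`` comments allowed);
    keys map 1:1 onto :class:`PipelineConfig` fields.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        raw = json.loads(text)
    else:
        raw = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        default = getattr(PipelineConfig, key)
        if isinstance(default, bool):
            kwargs[key] = value if isinstance(value, bool) else str(value).lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return PipelineConfig(**kwargs)
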