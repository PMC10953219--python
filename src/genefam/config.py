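"""Pipeline configuration: every tunable threshold in one place.

All randomness in the package flows from the single ``seed`` here; every
output file written by the CLI embeds the configuration digest so a run
can be tied to the exact thresholds that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class PipelineConfig:
    """Tunables for the whole survey pipeline.

    Parameters
    ----------
    redundancy_identity_cutoff : float
        Global-alignment identity at or above which two proteins are
        collapsed during redundancy reduction (1.0 keeps everything that
        is not an exact-identity duplicate).
    pair_min_identity : float
        Minimum identity for calling a paralogous pair (the classical
        "80% similar" rule).
    max_evalue : float
        E-value cutoff applied to the pairwise-alignment e-value proxy.
    tandem_cutoff_bp : int
        Same-chromosome nearest-edge distance at or below which a
        duplicate pair is tandem; beyond it (or across chromosomes) the
        pair is segmental. 5 Mb by convention.
    upstream_length : int
        Promoter length extracted upstream of the transcription start.
    clock_rate : float
        Synonymous substitution rate lambda, substitutions per
        synonymous site per year per lineage; divergence time is
        T = Ks / (2 * lambda).
    bootstrap_replicates : int
        Column-resampling replicates for bootstrap supports.
    ka_lambda, ka_k : float
        Karlin-Altschul-style constants of the e-value proxy
        E = k * m * n * N * exp(-lambda * score).
    pka_set : str
        Name of the pKa table used for isoelectric points ("emboss").
    seed : int
        Root seed for every stochastic stage.
    """

    redundancy_identity_cutoff: float = 1.00
    pair_min_identity: float = 0.80
    max_evalue: float = 1e-10
    tandem_cutoff_bp: int = 5_000_000
    upstream_length: int = 2000
    clock_rate: float = 6.5e-9
    bootstrap_replicates: int = 1000
    gap_open: float = 10.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    pka_set: str = "emboss"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("redundancy_identity_cutoff", "pair_min_identity",
                     "max_evalue", "tandem_cutoff_bp", "upstream_length",
                     "clock_rate", "bootstrap_replicates", "gap_open",
                     "gap_extend", "ka_lambda", "ka_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be strictly positive")

    def digest(self) -> str:
        """Stable short hash of the full configuration."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
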