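"""Run configuration: one YAML file, one global seed, derived stage seeds."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import ClassifierConfig
from .lesion import DEFAULT_AREAS
from .synthetic import GeneratorConfig


def derive_stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class RunConfig:
    generator: GeneratorConfig
    classifier: ClassifierConfig
    areas: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_AREAS))
    bootstrap_n_iter: int = 1000
    emphasis_images: int = 32     # validation images used for emphasis tables
    heatmap_exports: int = 4
    include_blur: bool = True
    include_pairs: bool = True
    seed: int = 0
    bootstrap_seed: int = 0
    random_mask_seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        self.classifier.validate()
        if set(self.areas) != set(DEFAULT_AREAS):
            raise ValueError(f"areas keys must be exactly {sorted(DEFAULT_AREAS)}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        """Parse a run configuration; ``seed`` overrides the file's seed.

        The global seed deterministically derives the generator, classifier
        and bootstrap seeds, so one integer pins the entire run.
        """
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"could not parse {path}: {exc}") from exc
        try:
            gen = GeneratorConfig(**raw.get("generator", {}))
        except TypeError as exc:
            raise ValueError(f"{path}: bad generator config: {exc}") from exc
        cls_raw = dict(raw.get("classifier", {}))
        cls_raw.setdefault("n_classes", gen.n_identities)
        cls_raw.setdefault("input_size", gen.image_size)
        if "blocks" in cls_raw:
            cls_raw["blocks"] = tuple(tuple(b) for b in cls_raw["blocks"])
        try:
            clf = ClassifierConfig(**cls_raw)
        except TypeError as exc:
            raise ValueError(f"{path}: bad classifier config: {exc}") from exc
        cfg = cls(generator=gen, classifier=clf,
                  areas=dict(raw.get("areas", DEFAULT_AREAS)),
                  bootstrap_n_iter=int(raw.get("bootstrap", {}).get("n_iter", 1000)),
                  emphasis_images=int(raw.get("emphasis_images", 32)),
                  heatmap_exports=int(raw.get("heatmap_exports", 4)),
                  include_blur=bool(raw.get("include_blur", True)),
                  include_pairs=bool(raw.get("include_pairs", True)),
                  seed=int(raw.get("seed", 0)))
        if seed is not None:
            cfg.seed = int(seed)
        gen_seed, clf_seed, boot_seed, rand_seed = derive_stage_seeds(cfg.seed)
        cfg.generator.seed = gen_seed
        cfg.classifier.seed = clf_seed
        cfg.bootstrap_seed = boot_seed
        cfg.random_mask_seed = rand_seed
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        from dataclasses import asdict
        return {"generator": asdict(self.generator),
                "classifier": asdict(self.classifier),
                "areas": self.areas, "bootstrap_n_iter": self.bootstrap_n_iter,
                "seed": self.seed, "bootstrap_seed": self.bootstrap_seed,
                "random_mask_seed": self.random_mask_seed}


def write_default_config(path) -> None:
    """Write a desk-scale default run configuration."""
    doc = {
        "generator": {"n_identities": 32, "images_per_identity": 50},
        "classifier": {"epochs": 15},
        "bootstrap": {"n_iter": 1000},
        "seed": 0,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
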