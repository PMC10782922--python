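"""Run configuration: every exposed hyperparameter with its default, plus a
lossless flat key=value text serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .types import ValidationError


@dataclass
class RunConfig:
    tfidf_variant: str = "signac"
    scale_factor: float = 1e4
    n_pcs: int = 100
    min_cell_fraction: float = 0.01
    corr_method: str = "pcc"
    chunk_size: int = 1000
    n_workers: int = 1
    n_fits: int = 3
    trim_quantiles: tuple[float, float] = (0.05, 0.95)
    frac: float = 0.3
    k: int = 20000
    seed: int = 0

    def validate(self) -> None:
        if self.tfidf_variant not in ("signac", "origin", "scopen"):
            raise ValidationError(f"invalid tfidf_variant {self.tfidf_variant!r}")
        if self.corr_method not in ("pcc", "spcc", "csc"):
            raise ValidationError(f"invalid corr_method {self.corr_method!r}")
        lo, hi = self.trim_quantiles
        if not 0 < lo < hi < 1:
            raise ValidationError(f"invalid trim_quantiles {self.trim_quantiles}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.n_pcs < 2:
            raise ValidationError("n_pcs must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trim_quantiles"] = list(self.trim_quantiles)
        return d

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"config line {ln}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValidationError(f"config line {ln}: unknown key {key!r}")
            kwargs[key] = _parse(key, raw.strip())
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


_STR_KEYS = {"tfidf_variant", "corr_method"}
_INT_KEYS = {"n_pcs", "chunk_size", "n_workers", "n_fits", "k", "seed"}


def _parse(key: str, raw: str):
    if key == "trim_quantiles":
        parts = raw.split(",")
        if len(parts) != 2:
            raise ValidationError(f"trim_quantiles needs two values, got {raw!r}")
        return (float(parts[0]), float(parts[1]))
    if key in _STR_KEYS:
        return raw
    if key in _INT_KEYS:
        return int(raw)
    return float(raw)
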