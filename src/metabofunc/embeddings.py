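"""Per-molecule SMILES-transformer embeddings behind a pluggable provider.

The default production backend mean-pools the per-token hidden vectors of a
pretrained ChemBERTa-style SMILES transformer (dimension 600), excluding
padding/special tokens from the mean.  The transformer stack is an optional
dependency; the ``deterministic_stub`` backend produces a pure, unit-norm
pseudo-random vector keyed by the canonical SMILES so the whole pipeline
(and its tests) runs offline with zero network access.

Providers are pure: the same molecule always yields the same vector, and the
batch API caches by canonical SMILES.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingProvider", "embed_batch", "CACHE_VERSION"]

CACHE_VERSION = 1
DEFAULT_CHECKPOINT = "seyonec/PubChem10M_SMILES_BPE_450k"


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class EmbeddingProvider:
    name: str = "stub-600"
    dim: int = 600
    backend: str = "deterministic_stub"  # or "pretrained_transformer"
    checkpoint: str = DEFAULT_CHECKPOINT
    hidden_layer: int = -1  # which hidden layer to pool (pretrained backend)
    n_calls: int = field(default=0, repr=False)
    _model: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.backend not in ("deterministic_stub", "pretrained_transformer"):
            raise ValueError(f"unknown embedding backend {self.backend!r}")
        if self.backend == "pretrained_transformer":
            self._load_transformer()

    def _load_transformer(self):
        try:
            from transformers import AutoModel, AutoTokenizer  # optional dependency
        except ImportError as exc:
            raise ImportError(
                "the pretrained_transformer backend requires the 'transformers' "
                "package; use backend='deterministic_stub' for offline runs"
            ) from exc
        tokenizer = AutoTokenizer.from_pretrained(self.checkpoint)
        model = AutoModel.from_pretrained(self.checkpoint)
        model.eval()
        hidden = model.config.hidden_size
        if hidden != self.dim:
            raise ValueError(
                f"model hidden size {hidden} does not match provider dim {self.dim}"
            )
        self._model = (tokenizer, model)

    def embed(self, smiles: str) -> np.ndarray:
        """Embedding vector of length ``dim`` for one molecule."""
        can = canonical_smiles(smiles)
        self.n_calls += 1
        if self.backend == "deterministic_stub":
            digest = hashlib.sha256(can.encode()).digest()
            seed = int.from_bytes(digest[:4], "big")  # < 2**32
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(self.dim)
            return v / np.linalg.norm(v)
        tokenizer, model = self._model
        import torch

        with torch.no_grad():
            enc = tokenizer(can, return_tensors="pt")
            out = model(**enc, output_hidden_states=True)
            hidden = out.hidden_states[self.hidden_layer][0]
            mask = enc["attention_mask"][0].bool()
            special = tokenizer.get_special_tokens_mask(
                enc["input_ids"][0].tolist(), already_has_special_tokens=True
            )
            keep = mask & ~torch.tensor(special, dtype=torch.bool)
            if keep.sum() == 0:
                keep = mask
            return hidden[keep].mean(dim=0).numpy().astype(np.float64)


def _load_cache(cache_path: Path, provider: EmbeddingProvider) -> dict[str, list[float]]:
    if not cache_path.exists():
        return {}
    try:
        blob = json.loads(cache_path.read_text())
        if blob.get("version") != CACHE_VERSION:
            raise ValueError("cache version mismatch")
        if blob.get("provider") != provider.name or blob.get("dim") != provider.dim:
            raise ValueError("cache provider mismatch")
        return blob["vectors"]
    except (ValueError, KeyError, json.JSONDecodeError):
        logger.warning("corrupt embedding cache %s; rebuilding", cache_path)
        return {}


def embed_batch(
    provider: EmbeddingProvider,
    smiles_list: list[str],
    cache_path=None,
) -> tuple[np.ndarray, dict]:
    """Embed a list of SMILES, caching by canonical SMILES.

    Returns the (len(smiles_list), dim) matrix and a stats dict with cache
    hit/miss counts.  Duplicate molecules are computed once.
    """
    cache: dict[str, list[float]] = {}
    path = Path(cache_path) if cache_path is not None else None
    if path is not None:
        cache = _load_cache(path, provider)
    stats = {"hits": 0, "misses": 0}
    out = np.zeros((len(smiles_list), provider.dim), dtype=np.float64)
    for i, smi in enumerate(smiles_list):
        can = canonical_smiles(smi)
        if can in cache:
            stats["hits"] += 1
        else:
            cache[can] = provider.embed(can).tolist()
            stats["misses"] += 1
        out[i] = cache[can]
    if path is not None:
        path.write_text(json.dumps({
            "version": CACHE_VERSION,
            "provider": provider.name,
            "dim": provider.dim,
            "vectors": cache,
        }))
    return out, stats
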