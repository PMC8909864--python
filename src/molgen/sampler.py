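"""Autoregressive sampling with temperature and campaign orchestration.

Sampling walks the trained network one character at a time: the begin
sentinel (plus an optional rooted-scaffold prefix) primes the hidden state,
then characters are drawn from the temperature-adjusted next-character
distribution until the end sentinel ``E`` or the length cap.  Temperature T
reshapes a probability vector p as p^(1/T) renormalised — T < 1 sharpens
toward the argmax (conservative, more valid strings), T > 1 flattens
(diverse, more invalid strings).

A sampling campaign crosses model checkpoints x temperatures x scaffold
attachment positions, drawing ``n_samples`` strings per cell with a
deterministic per-cell sub-seed, so any single cell can be reproduced in
isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .codec import CodecError
from .generator import GeneratorModel


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SamplingConfig:
    temperature: float = 1.0
    n_samples: int = 1
    max_len: int = 140  # total token budget per string, prefix included
    seed: int = 0
    prefix: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise SamplingError("temperature must be > 0")
        if self.max_len <= len(self.prefix) + 2:
            raise SamplingError("max_len must exceed len(prefix) + 2")
        if self.n_samples < 1:
            raise SamplingError("n_samples must be >= 1")


def apply_temperature(p: np.ndarray, T: float) -> np.ndarray:
    """Reshape a categorical distribution: q_i = p_i^(1/T) / sum_j p_j^(1/T).

    The transform is monotone in p for every T, so probability ordering is
    preserved; T=1 is the identity, T->0 approaches one-hot at the argmax.
    """
    if T <= 0:
        raise SamplingError("temperature must be > 0")
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise SamplingError("input must be a probability vector")
    if T == 1.0:
        return p.copy()
    with np.errstate(divide="ignore"):
        logp = np.log(p)  # zeros stay zero probability
    logq = logp / T
    logq -= logq.max()
    q = np.exp(logq)
    s = q.sum()
    if s == 0 or not np.isfinite(s):
        raise SamplingError("degenerate probability vector")
    return q / s


def sample_batch(model: GeneratorModel, config: SamplingConfig) -> pd.DataFrame:
    """Draw ``n_samples`` strings in one batched pass.

    Returns a DataFrame with columns ``smiles`` (prefix + generated
    characters, sentinels stripped) and ``terminated_by_E``.  Strings that
    hit ``max_len`` without emitting ``E`` are flagged and count as invalid
    downstream.
    """
    vocab = model.vocab
    for pos, ch in enumerate(config.prefix):
        if ch not in vocab.index:
            raise CodecError(f"prefix character {ch!r} at position {pos} not in vocabulary")

    rng = np.random.default_rng(config.seed)
    B = config.n_samples
    V = len(vocab)
    U = model.config.lstm_units

    prime = [vocab.begin_index] + [vocab.index[c] for c in config.prefix]
    h1 = np.zeros((B, U)); c1 = np.zeros((B, U))
    h2 = np.zeros((B, U)); c2 = np.zeros((B, U))
    probs = None
    for j in prime:
        x = np.zeros((B, V)); x[:, j] = 1.0
        h1, c1 = model.lstm1.step(x, h1, c1)
        h2, c2 = model.lstm2.step(h1, h2, c2)
    probs = model.dense.forward(h2[:, None, :])[:, 0, :]

    budget = config.max_len - len(prime)
    generated = np.full((B, budget), -1, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    inv_T = 1.0 / config.temperature
    for t in range(budget):
        if config.temperature != 1.0:
            with np.errstate(divide="ignore"):
                logq = np.log(probs) * inv_T
            logq -= logq.max(axis=1, keepdims=True)
            q = np.exp(logq)
            q /= q.sum(axis=1, keepdims=True)
        else:
            q = probs
        u = rng.random((B, 1))
        draws = (q.cumsum(axis=1) > u).argmax(axis=1)
        draws[done] = vocab.end_index
        generated[:, t] = np.where(done, -1, draws)
        done |= draws == vocab.end_index
        if done.all():
            break
        x = np.zeros((B, V)); x[np.arange(B), draws] = 1.0
        h1, c1 = model.lstm1.step(x, h1, c1)
        h2, c2 = model.lstm2.step(h1, h2, c2)
        probs = model.dense.forward(h2[:, None, :])[:, 0, :]

    smiles, terminated = [], []
    for row in range(B):
        chars = []
        for j in generated[row]:
            if j < 0 or j == vocab.end_index:
                break
            chars.append(vocab.tokens[j])
        terminated.append(bool(done[row]))
        smiles.append(config.prefix + "".join(chars))
    return pd.DataFrame({"smiles": smiles, "terminated_by_E": terminated})


def sample_one(model: GeneratorModel, config: SamplingConfig) -> str:
    """Draw a single string (prefix preserved verbatim, sentinels stripped)."""
    return sample_batch(model, replace(config, n_samples=1))["smiles"].iloc[0]


def cell_seed(seed: int, checkpoint: object, temperature: float, site: object) -> int:
    """Deterministic sub-seed for one campaign cell, stable across runs."""
    key = f"{seed}|{checkpoint}|{temperature:.6g}|{site}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def plan_campaign(
    checkpoint_ids: list,
    site_ids: list,
    temperatures: list[float],
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Row skeleton of a sampling campaign, one row per string to draw.

    The row count is |checkpoints| x |temperatures| x |sites| x n_samples —
    for the four-epoch, four-temperature, seven-position, 2000-sample
    production plan that is 224,000 rows — and can be audited before any
    model inference happens.
    """
    if n_samples < 1:
        raise SamplingError("n_samples must be >= 1")
    rows = []
    for ck in checkpoint_ids:
        for T in temperatures:
            for site in site_ids:
                sub = cell_seed(seed, ck, T, site)
                rows.append((ck, T, site, n_samples, sub))
    plan = pd.DataFrame(rows, columns=["checkpoint", "temperature", "site", "n_samples", "cell_seed"])
    return plan.loc[plan.index.repeat(plan["n_samples"])].reset_index(drop=True)


def run_campaign(
    checkpoints: dict[object, GeneratorModel],
    rooted_library: list,
    temperatures: list[float],
    n_samples: int,
    seed: int = 0,
    max_len: int = 140,
) -> pd.DataFrame:
    """Execute a full campaign; one DataFrame row per sampled string.

    ``rooted_library`` holds RootedScaffoldSMILES entries (site id taken
    from their attachment atom index).  Identical seeds reproduce identical
    tables; each cell is independently reproducible from its sub-seed.
    """
    out = []
    for ck_id, model in checkpoints.items():
        if model is None:
            raise SamplingError(f"missing checkpoint {ck_id!r}")
        for T in temperatures:
            for rooted in rooted_library:
                site_id = rooted.site.atom_index
                sub = cell_seed(seed, ck_id, T, site_id)
                cfg = SamplingConfig(
                    temperature=T, n_samples=n_samples, max_len=max_len,
                    seed=sub, prefix=rooted.smiles,
                )
                cell = sample_batch(model, cfg)
                cell.insert(0, "checkpoint", ck_id)
                cell.insert(1, "temperature", T)
                cell.insert(2, "site", site_id)
                out.append(cell)
    return pd.concat(out, ignore_index=True)
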