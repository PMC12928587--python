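"""Mask training: learn a binary weight mask over a frozen masked LM.

Each optimization step draws one suppression minibatch and one maintenance
minibatch of equal size, samples a fresh Gumbel-sigmoid mask, and takes an
Adam step on the mask logits alone — the model weights are frozen and are
verified unchanged (by cryptographic hash) at the end of training.  Every
``snapshot_every`` steps the deterministic (noise-free) mask is evaluated
on the validation split under a composite criterion — reward suppression,
penalize maintenance degradation beyond a tolerance.  The snapshot
returned is the *earliest* one within a margin of the best composite:
sparsity only grows with further training, so the earliest plateau
snapshot is the most parsimonious subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._batch import encode_records, pad_batch
from .annotations import (
    ConfigError,
    DomainRecord,
    Partition,
    SplitAssignment,
    SuppressionSpec,
    build_partition,
    split_dataset,
)
from .autodiff import Adam, Tensor
from .masking import MaskState, binarize, sample_scores, sparsity
from .objectives import (
    LossWeights,
    apply_plan,
    combine,
    maintenance_kl,
    make_corruption_plan,
    mlm_loss,
    perplexity,
    suppression_loss,
)

__all__ = ["TrainConfig", "TrainResult", "train_subnetwork", "make_control_spec"]


@dataclass
class TrainConfig:
    """Defaults for mask learning; every field is serialized with each run."""

    weights: LossWeights = field(default_factory=lambda: LossWeights(2.0, 1.0, 1.0))
    tau: float = 0.5
    threshold: float = 0.5
    logit_init: float = -5.0
    logit_init_jitter: float = 0.0  # stddev of optional random spread around logit_init
    lr: float = 5e-2
    adam_eps: float = 1e-4
    optimizer: str = "adam"
    max_steps: int = 1000
    batch_size: int = 16
    snapshot_every: int = 100
    patience: int = 5  # snapshots without composite improvement
    snapshot_margin: float = 0.1  # parsimony: earliest snapshot within margin of best
    maint_tolerance: float = 0.10
    maint_penalty: float = 50.0
    corruption_rate: float = 0.15
    action_mix: tuple[float, float, float] = (0.80, 0.10, 0.10)
    mask_seed: int = 0
    noise_seed: int = 0
    data_seed: int = 1
    eval_rate: float = 0.15
    eval_rounds: int = 2
    eval_max_records: int = 32

    def __post_init__(self):
        if self.max_steps < 0:
            raise ConfigError("max_steps must be >= 0")
        for name in ("tau", "lr", "batch_size", "snapshot_every"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = [
            self.weights.suppression, self.weights.maintenance, self.weights.mlm
        ]
        return d


@dataclass
class TrainResult:
    mask: MaskState
    log: pd.DataFrame
    config: TrainConfig
    best_step: int
    best_composite: float


def _gather_rows(probs, rows, cols):
    return probs[np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)]


def _scorable(tokens: np.ndarray, positions: np.ndarray, aa: int) -> np.ndarray:
    """Restrict positions to those whose true token is a canonical residue."""
    return positions[tokens[positions] < aa]


class _SubnetTrainer:
    def __init__(self, model, records, partition: Partition, cfg: TrainConfig,
                 split: SplitAssignment):
        self.model = model
        self.vocab = model.vocab
        self.aa = self.vocab.amino_acid_count
        self.cfg = cfg
        self.partition = partition
        self.split = split
        self.by_id = {r.id: r for r in records}
        self.tokens = encode_records(records, self.vocab)
        self._base_cache: dict[str, np.ndarray] = {}

        train_ids = [i for i in split.ids("train") if i in self.by_id]
        val_ids = [i for i in split.ids("validation") if i in self.by_id]
        if partition.level == "sequence":
            self.supp_train = [i for i in train_ids if i in partition.suppressed_ids]
            self.maint_train = [i for i in train_ids if i in partition.maintained_ids]
            self.supp_val = [i for i in val_ids if i in partition.suppressed_ids]
            self.maint_val = [i for i in val_ids if i in partition.maintained_ids]
            if not self.supp_train or not self.maint_train:
                raise ConfigError(
                    "training split leaves one side of the partition empty"
                )
        else:
            self.supp_train = self.maint_train = train_ids
            self.supp_val = self.maint_val = val_ids
            if not any(
                partition.suppressed_positions(i).size for i in train_ids
            ):
                raise ConfigError("no suppressed positions in the training split")

    # -- baselines -----------------------------------------------------
    def baseline_probs(self, ids: list[str]) -> dict[str, np.ndarray]:
        missing = [i for i in ids if i not in self._base_cache]
        for start in range(0, len(missing), self.cfg.batch_size):
            chunk = missing[start : start + self.cfg.batch_size]
            batch, lengths = pad_batch([self.tokens[i] for i in chunk], self.vocab.pad_id)
            probs = self.model.forward(batch).data
            for bi, rid in enumerate(chunk):
                self._base_cache[rid] = probs[bi, : lengths[bi]]
        return {i: self._base_cache[i] for i in ids}

    # -- one optimization step ------------------------------------------
    def losses(self, m: Tensor, rng_data) -> tuple:
        cfg = self.cfg
        if self.partition.level == "sequence":
            supp_ids = [self.supp_train[j] for j in rng_data.choice(
                len(self.supp_train),
                size=min(cfg.batch_size, len(self.supp_train)), replace=False)]
            maint_ids = [self.maint_train[j] for j in rng_data.choice(
                len(self.maint_train),
                size=min(cfg.batch_size, len(self.maint_train)), replace=False)]
            ls = self._suppression_sequence(m, supp_ids)
            lm = self._maintenance_kl_ids(m, maint_ids, restrict=None)
            lmlm = self._mlm(m, maint_ids, rng_data, restrict_supp=False)
        else:
            ids = [self.supp_train[j] for j in rng_data.choice(
                len(self.supp_train),
                size=min(cfg.batch_size, len(self.supp_train)), replace=False)]
            ls, lm = self._residue_clean_losses(m, ids)
            lmlm = self._mlm(m, ids, rng_data, restrict_supp=True)
        return ls, lm, lmlm

    def _suppression_sequence(self, m, ids):
        batch, lengths = pad_batch([self.tokens[i] for i in ids], self.vocab.pad_id)
        probs = self.model.forward(batch, mask=m)
        rows, cols = [], []
        for bi, rid in enumerate(ids):
            t = self.tokens[rid]
            pos = _scorable(t, np.arange(t.size), self.aa)
            rows.extend([bi] * pos.size)
            cols.extend(pos.tolist())
        return suppression_loss(_gather_rows(probs, rows, cols))

    def _maintenance_kl_ids(self, m, ids, restrict):
        batch, lengths = pad_batch([self.tokens[i] for i in ids], self.vocab.pad_id)
        probs = self.model.forward(batch, mask=m)
        base = self.baseline_probs(ids)
        rows, cols, base_rows = [], [], []
        for bi, rid in enumerate(ids):
            t = self.tokens[rid]
            pos = np.arange(t.size) if restrict is None else restrict[rid]
            pos = _scorable(t, pos, self.aa)
            rows.extend([bi] * pos.size)
            cols.extend(pos.tolist())
            base_rows.append(base[rid][pos])
        return maintenance_kl(
            _gather_rows(probs, rows, cols), np.concatenate(base_rows)
        )

    def _residue_clean_losses(self, m, ids):
        batch, lengths = pad_batch([self.tokens[i] for i in ids], self.vocab.pad_id)
        probs = self.model.forward(batch, mask=m)
        base = self.baseline_probs(ids)
        s_rows, s_cols = [], []
        m_rows, m_cols, m_base = [], [], []
        for bi, rid in enumerate(ids):
            t = self.tokens[rid]
            jstar = _scorable(t, self.partition.suppressed_positions(rid), self.aa)
            jprime = _scorable(t, self.partition.maintained_positions(rid), self.aa)
            s_rows.extend([bi] * jstar.size)
            s_cols.extend(jstar.tolist())
            m_rows.extend([bi] * jprime.size)
            m_cols.extend(jprime.tolist())
            m_base.append(base[rid][jprime])
        ls = suppression_loss(_gather_rows(probs, s_rows, s_cols))
        lm = maintenance_kl(
            _gather_rows(probs, m_rows, m_cols), np.concatenate(m_base)
        )
        return ls, lm

    def _mlm(self, m, ids, rng_data, restrict_supp: bool):
        cfg = self.cfg
        corrupted, plans = [], []
        for rid in ids:
            t = self.tokens[rid]
            plan = make_corruption_plan(t.size, cfg.corruption_rate, cfg.action_mix, seed=rng_data)
            plans.append(plan)
            corrupted.append(apply_plan(t, plan, self.vocab))
        batch, lengths = pad_batch(corrupted, self.vocab.pad_id)
        probs = self.model.forward(batch, mask=m)
        terms = []
        for bi, (rid, plan) in enumerate(zip(ids, plans)):
            t = self.tokens[rid]
            supp = (
                self.partition.suppressed_positions(rid) if restrict_supp else None
            )
            scored = plan.positions
            if supp is not None:
                scored = np.setdiff1d(scored, supp)
            if _scorable(t, scored, self.aa).size == 0:
                continue
            terms.append(
                mlm_loss(probs[bi, 0 : t.size], t, plan, suppressed_positions=supp)
            )
        if not terms:
            return Tensor(0.0)
        total = terms[0]
        for term in terms[1:]:
            total = total + term
        return total * (1.0 / len(terms))

    # -- validation snapshots --------------------------------------------
    def composite(self, state: MaskState) -> tuple[float, dict]:
        from .evaluation import evaluation_nlls

        cfg = self.cfg
        m = state.mask()
        supp_ids = self.supp_val[: cfg.eval_max_records] or self.supp_train[: cfg.eval_max_records]
        maint_ids = self.maint_val[: cfg.eval_max_records] or self.maint_train[: cfg.eval_max_records]
        recs = [self.by_id[i] for i in dict.fromkeys(supp_ids + maint_ids)]
        sub = evaluation_nlls(self.model, recs, mask=m, rate=cfg.eval_rate,
                              seed=cfg.data_seed, rounds=cfg.eval_rounds)
        base = evaluation_nlls(self.model, recs, mask=None, rate=cfg.eval_rate,
                               seed=cfg.data_seed, rounds=cfg.eval_rounds)

        def pool(nlls, ids, side):
            vals = []
            for rid in ids:
                pos, v = nlls[rid]
                if self.partition.level == "residue":
                    target = (
                        self.partition.suppressed_positions(rid)
                        if side == "supp"
                        else self.partition.maintained_positions(rid)
                    )
                    v = v[np.isin(pos, target)]
                if v.size:
                    vals.append(v)
            return perplexity(np.concatenate(vals)) if vals else np.nan

        ppl = {
            "supp_sub": pool(sub, supp_ids, "supp"),
            "supp_base": pool(base, supp_ids, "supp"),
            "maint_sub": pool(sub, maint_ids, "maint"),
            "maint_base": pool(base, maint_ids, "maint"),
        }
        ratio_supp = ppl["supp_sub"] / ppl["supp_base"]
        ratio_maint = ppl["maint_sub"] / ppl["maint_base"]
        score = ratio_supp - cfg.maint_penalty * max(
            0.0, ratio_maint - 1.0 - cfg.maint_tolerance
        )
        metrics = dict(ppl, ratio_supp=ratio_supp, ratio_maint=ratio_maint)
        return float(score), metrics


def train_subnetwork(
    model,
    records: list[DomainRecord],
    spec: SuppressionSpec | Partition,
    config: TrainConfig | None = None,
    split: SplitAssignment | None = None,
) -> TrainResult:
    """Learn a mask suppressing ``spec`` on the train split of ``records``.

    Returns the snapshot with the best validation composite; the model's
    weights are verified bit-identical before and after.
    """
    cfg = config or TrainConfig()
    partition = spec if isinstance(spec, Partition) else build_partition(records, spec)
    if split is None:
        split = split_dataset(records, seed=cfg.data_seed)
    trainer = _SubnetTrainer(model, records, partition, cfg, split)

    hash_before = model.weights_hash()
    k = model.num_maskable
    init_logits = np.full(k, cfg.logit_init)
    if cfg.logit_init_jitter > 0:
        init_logits += np.random.default_rng(cfg.mask_seed).normal(
            0.0, cfg.logit_init_jitter, size=k
        )
    state = MaskState(init_logits, tau=cfg.tau, threshold=cfg.threshold,
                      noise_seed=cfg.noise_seed)
    logits_t = Tensor(state.logits, requires_grad=True)
    opt = Adam([logits_t], lr=cfg.lr, eps=cfg.adam_eps)
    rng_noise = np.random.default_rng(cfg.noise_seed)
    rng_data = np.random.default_rng(cfg.data_seed)

    rows = []
    snapshots: list[tuple[int, np.ndarray, float]] = []
    best_score, stall = -np.inf, 0
    for step in range(cfg.max_steps):
        u = rng_noise.random(k)
        s = sample_scores(logits_t, cfg.tau, u)
        m = binarize(s, cfg.threshold)
        ls, lm, lmlm = trainer.losses(m, rng_data)
        total = combine((ls, lm, lmlm), cfg.weights)
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"non-finite loss at step {step}: "
                f"supp={ls.data} maint={lm.data} mlm={lmlm.data}"
            )
        opt.zero_grad()
        total.backward()
        opt.step()
        row = {
            "step": step,
            "loss_suppression": float(ls.data),
            "loss_maintenance": float(lm.data),
            "loss_mlm": float(lmlm.data),
            "loss_total": float(total.data),
            "sparsity_percent": sparsity(
                MaskState(logits_t.data, cfg.tau, cfg.threshold).mask()
            ),
        }
        if (step + 1) % cfg.snapshot_every == 0:
            snap = MaskState(logits_t.data.copy(), cfg.tau, cfg.threshold, cfg.noise_seed)
            score, metrics = trainer.composite(snap)
            row.update(
                composite=score,
                val_ratio_supp=metrics["ratio_supp"],
                val_ratio_maint=metrics["ratio_maint"],
            )
            snapshots.append((step + 1, logits_t.data.copy(), score))
            if score > best_score:
                best_score, stall = score, 0
            else:
                stall += 1
            if stall >= cfg.patience:
                rows.append(row)
                break
        rows.append(row)

    hash_after = model.weights_hash()
    if hash_after != hash_before:
        raise RuntimeError("model weights changed during mask training")
    # Parsimony rule: sparsity grows with training, so among snapshots whose
    # composite reaches the plateau (within snapshot_margin of the best), the
    # earliest one carries the least incidental pruning.
    if snapshots:
        best_step, best_logits, best_score = next(
            snap for snap in snapshots if snap[2] >= best_score - cfg.snapshot_margin
        )
    else:
        best_step, best_logits, best_score = 0, state.logits.copy(), 0.0
    final = MaskState(best_logits, cfg.tau, cfg.threshold, cfg.noise_seed)
    return TrainResult(
        mask=final,
        log=pd.DataFrame(rows),
        config=cfg,
        best_step=best_step,
        best_composite=float(best_score),
    )


def make_control_spec(
    records: list[DomainRecord],
    kind: str,
    n: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> Partition:
    """Control partitions: N random sequences, or a random fraction of residues.

    ``random_sequences`` draws ``n`` record ids uniformly without
    replacement; ``random_residues`` marks each position suppressed
    independently with probability ``fraction``.
    """
    rng = np.random.default_rng(seed)
    ids = [r.id for r in records]
    if kind == "random_sequences":
        if n is None or n <= 0:
            raise ConfigError("random_sequences control requires n >= 1")
        if n > len(ids):
            raise ConfigError(f"n={n} exceeds pool of {len(ids)} records")
        chosen = {ids[j] for j in rng.choice(len(ids), size=n, replace=False)}
        return Partition(
            level="sequence",
            suppressed_ids=frozenset(chosen),
            maintained_ids=frozenset(set(ids) - chosen),
        )
    if kind == "random_residues":
        if fraction is None or not 0.0 < fraction < 1.0:
            raise ConfigError("random_residues control requires fraction in (0,1)")
        positions, lengths = {}, {}
        for r in records:
            draw = rng.random(len(r)) < fraction
            positions[r.id] = np.nonzero(draw)[0]
            lengths[r.id] = len(r)
        return Partition(
            level="residue",
            suppressed_ids=frozenset(ids),
            maintained_ids=frozenset(ids),
            residue_positions=positions,
            record_lengths=lengths,
        )
    raise ConfigError(f"unknown control kind {kind!r}")
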