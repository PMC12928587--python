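"""Evaluation: stratified perplexity, per-layer pruning profiles, Δmetric tests.

Perplexity is measured MLM-style: per sequence, a seeded 15% of positions
are replaced by the mask token and the NLL of the true residue is recorded
at those positions.  The *same* corrupted inputs are fed to the subnetwork
and to the unmasked baseline, so any difference is attributable to the
mask.  For residue-level suppression the suppression cell scores only J*
positions and the maintenance cell only J'.

Structure metrics (RMSD / TM-score / pLDDT) are consumed from a table —
this package never runs folding.  For each metric and input the change
Δ = metric_subnet − metric_baseline is tested with a paired t-test per set
(suppression, maintenance) and the magnitudes |Δ_supp| vs |Δ_maint| with a
two-sample Kolmogorov–Smirnov test (exact for small samples, asymptotic
otherwise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import encode_records, pad_batch
from .annotations import AnnotationError, ConfigError, Partition, SplitAssignment
from .masking import MaskState, sparsity
from .objectives import perplexity

__all__ = [
    "EvalReport",
    "DeltaMetricReport",
    "evaluation_nlls",
    "stratified_perplexity",
    "per_layer_pruning",
    "delta_metric_stats",
]

_PARTS = ("train", "validation", "test")


@dataclass
class EvalReport:
    """Perplexity for {subnetwork, baseline} x {suppression, maintenance} x split."""

    perplexities: dict[tuple[str, str, str], float | None]
    sparsity: float
    per_layer: pd.DataFrame

    def cell(self, model: str, side: str, part: str) -> float | None:
        return self.perplexities.get((model, side, part))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "side": s, "split": p, "perplexity": v}
            for (m, s, p), v in sorted(self.perplexities.items())
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sparsity_percent": self.sparsity,
            "perplexity": {
                f"{m}/{s}/{p}": v for (m, s, p), v in sorted(self.perplexities.items())
            },
            "per_layer_pruned_percent": {
                str(int(r.layer)): float(r.pruned_percent)
                for r in self.per_layer.itertuples()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class DeltaMetricReport:
    """Per-metric paired-t and KS statistics on structure-metric changes."""

    metrics: dict[str, dict]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.metrics, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluation_nlls(
    model,
    records,
    mask: np.ndarray | None = None,
    rate: float = 0.15,
    seed: int = 0,
    rounds: int = 1,
    batch_size: int = 16,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-record (positions, NLLs) at seeded mask-token corruption positions.

    Deterministic in ``seed`` and the order of ``records``; calling twice
    with the same seed (e.g. once with a mask, once without) scores the two
    models on identical corrupted inputs.
    """
    vocab = model.vocab
    tokens = encode_records(records, vocab)
    rng = np.random.default_rng(seed)
    items = []  # (record_id, corrupted, scored_positions, targets)
    for r in records:
        t = tokens[r.id]
        for _ in range(rounds):
            sel = np.nonzero(rng.random(t.size) < rate)[0]
            sel = sel[t[sel] < vocab.amino_acid_count]
            if sel.size == 0:
                continue
            corrupted = t.copy()
            corrupted[sel] = vocab.mask_id
            items.append((r.id, corrupted, sel, t[sel]))

    out: dict[str, list] = {r.id: [] for r in records}
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        batch, _ = pad_batch([c[1] for c in chunk], vocab.pad_id)
        logp = model.forward(batch, mask=mask, return_log=True).data
        for bi, (rid, _c, sel, tgt) in enumerate(chunk):
            out[rid].append((sel, -logp[bi, sel, tgt]))
    final = {}
    for rid, parts in out.items():
        if parts:
            final[rid] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        else:
            final[rid] = (np.empty(0, dtype=np.intp), np.empty(0))
    return final


def _stratum_perplexity(
    nlls: dict[str, tuple[np.ndarray, np.ndarray]],
    ids: list[str],
    positions_of: dict[str, np.ndarray] | None,
) -> float | None:
    pool = []
    for rid in ids:
        pos, vals = nlls[rid]
        if positions_of is not None:
            keep = np.isin(pos, positions_of[rid])
            vals = vals[keep]
        if vals.size:
            pool.append(vals)
    if not pool:
        return None
    return perplexity(np.concatenate(pool))


def stratified_perplexity(
    model,
    mask_state: MaskState | np.ndarray,
    records,
    split: SplitAssignment,
    partition: Partition,
    rate: float = 0.15,
    seed: int = 0,
    rounds: int = 1,
) -> EvalReport:
    """Fig-2-style report: subnetwork vs baseline perplexity per stratum.

    Empty strata are reported as absent (None), not as zero.
    """
    m = mask_state.mask() if isinstance(mask_state, MaskState) else np.asarray(mask_state)
    by_id = {r.id: r for r in records}
    report: dict[tuple[str, str, str], float | None] = {}

    for part in _PARTS:
        part_records = [by_id[i] for i in split.ids(part) if i in by_id]
        if not part_records:
            for side in ("suppression", "maintenance"):
                report[("subnetwork", side, part)] = None
                report[("baseline", side, part)] = None
            continue
        sub_nlls = evaluation_nlls(model, part_records, mask=m, rate=rate, seed=seed, rounds=rounds)
        base_nlls = evaluation_nlls(model, part_records, mask=None, rate=rate, seed=seed, rounds=rounds)
        if partition.level == "sequence":
            supp_ids = [r.id for r in part_records if r.id in partition.suppressed_ids]
            maint_ids = [r.id for r in part_records if r.id in partition.maintained_ids]
            cells = {
                "suppression": (supp_ids, None),
                "maintenance": (maint_ids, None),
            }
        else:
            ids = [r.id for r in part_records]
            jstar = {i: partition.suppressed_positions(i) for i in ids}
            jprime = {i: partition.maintained_positions(i) for i in ids}
            cells = {
                "suppression": (ids, jstar),
                "maintenance": (ids, jprime),
            }
        for side, (ids_, posmap) in cells.items():
            report[("subnetwork", side, part)] = _stratum_perplexity(sub_nlls, ids_, posmap)
            report[("baseline", side, part)] = _stratum_perplexity(base_nlls, ids_, posmap)

    return EvalReport(
        perplexities=report,
        sparsity=sparsity(m),
        per_layer=per_layer_pruning(m, model),
    )


def per_layer_pruning(mask, model) -> pd.DataFrame:
    """Percent of maskable parameters pruned in each layer.

    The slot-weighted mean over layers equals the overall sparsity.
    """
    m = mask.mask() if isinstance(mask, MaskState) else np.asarray(mask, dtype=float)
    if m.size != model.num_maskable:
        raise ConfigError(
            f"mask length {m.size} does not match manifest size {model.num_maskable}"
        )
    layers = model.slot_layers()
    rows = []
    for layer in np.unique(layers):
        sel = m[layers == layer]
        rows.append(
            {
                "layer": int(layer),
                "n_slots": int(sel.size),
                "pruned_percent": float(100.0 * np.count_nonzero(sel == 0) / sel.size),
            }
        )
    return pd.DataFrame(rows)


def _ks_method(n1: int, n2: int) -> str:
    return "exact" if max(n1, n2) <= 25 else "asymp"


def delta_metric_stats(table: pd.DataFrame) -> DeltaMetricReport:
    """Paired-t per set and two-sample KS on |Δ| magnitudes, per metric.

    ``table`` columns: id, set_label in {suppression, maintenance},
    metric_name, value_subnet, value_baseline.  Pairing is by row (one id,
    both values); rows with a missing value raise an error listing the ids.
    """
    required = {"id", "set_label", "metric_name", "value_subnet", "value_baseline"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ConfigError(f"metric table missing columns {sorted(missing_cols)}")
    bad = table[table[["value_subnet", "value_baseline"]].isna().any(axis=1)]
    if len(bad):
        raise AnnotationError(f"unpaired metric rows for ids: {sorted(bad['id'])}")

    out: dict[str, dict] = {}
    for metric, sub in table.groupby("metric_name"):
        entry: dict = {}
        abs_deltas = {}
        for set_label in ("suppression", "maintenance"):
            rows = sub[sub["set_label"] == set_label]
            if len(rows) < 2:
                raise ConfigError(
                    f"need >= 2 paired rows in {set_label} set for {metric}, got {len(rows)}"
                )
            a = rows["value_subnet"].to_numpy(float)
            b = rows["value_baseline"].to_numpy(float)
            delta = a - b
            if np.allclose(delta, 0.0):
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = stats.ttest_rel(a, b)
            entry[set_label] = {
                "n": int(len(rows)),
                "mean_delta": float(delta.mean()),
                "t_statistic": float(t_stat),
                "p_value": float(p_val),
            }
            abs_deltas[set_label] = np.abs(delta)
        ks = stats.ks_2samp(
            abs_deltas["suppression"],
            abs_deltas["maintenance"],
            method=_ks_method(
                abs_deltas["suppression"].size, abs_deltas["maintenance"].size
            ),
        )
        entry["ks_statistic"] = float(ks.statistic)
        entry["ks_p_value"] = float(ks.pvalue)
        entry["mean_abs_delta_gap"] = float(
            abs_deltas["suppression"].mean() - abs_deltas["maintenance"].mean()
        )
        out[str(metric)] = entry
    return DeltaMetricReport(metrics=out)
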