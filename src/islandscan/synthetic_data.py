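"""Synthetic sort-seq datasets with known ground truth.

Emulates the wet-lab library end to end: 150 bp templates carrying a
planted −35/−10 promoter pair (spacer 15-20 bp) plus decoy boxes, mutant
daughters from an error-prone-PCR-like process (zero-truncated Poisson
mutation counts, mean ~2.5, capped at 10), a deterministic latent activity
model mapping PWM scores to a fluorescence score in [1, 4], and multinomial
read counts over four sorting bins with adjacent-bin spillover noise.

The activity model is a logistic of the best paired-box score — the
simplest model consistent with the pairing requirement and graded
fluorescence of real promoters; it is plumbing for recovery tests, not a
claim about sigma70 biophysics. The motif instance sets shipped here are
synthetic stand-ins whose matrices drive both simulation and recovery
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dna import BASES, encode, encode_many, revcomp
from .motif_scan import PWM, build_pwm
from .sortseq_io import COUNT_COLUMNS, ParentSequence, write_parents_fasta

# Synthetic aligned instance sets (hand-written around the canonical
# consensus hexamers) used to build the simulation matrices.
MINUS10_INSTANCES = [
    "TATAAT", "TATAAT", "TATAAT", "TATAAT", "TATAAT",
    "TACAAT", "TATACT", "TAGAAT", "CATAAT", "TATGAT",
    "TATATT", "GATAAT", "TATTAT", "TACACT",
]
MINUS35_INSTANCES = [
    "TTGACA", "TTGACA", "TTGACA", "TTGACA", "TTGACA",
    "TTGACT", "TTGATA", "TTTACA", "CTGACA", "TTGCCA",
    "TGGACA", "ATGACA", "TTGAGA", "TTCACA",
]

MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"


def default_pwms(pseudocount: float = 0.5) -> tuple[PWM, PWM]:
    """The simulation's −10 and −35 matrices (synthetic instance sets)."""
    return (
        build_pwm(MINUS10_INSTANCES, pseudocount, name="minus10"),
        build_pwm(MINUS35_INSTANCES, pseudocount, name="minus35"),
    )


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic sort-seq experiment.

    Defaults mirror the real library: 150 bp templates, ~2.5 point
    mutations per daughter (1-10), 2000 daughters per parent, reads
    multinomially spread over 4 bins per channel with 5% adjacent-bin
    spillover.
    """

    n_templates: int = 10
    seq_length: int = 150
    gc_content: float = 0.5
    plant_promoter: bool = True
    spacer: int | None = 17  # None -> uniform in [15, 20] per template
    n_decoys: int = 2
    hns_site: str | None = None  # planted repressor motif sequence
    hns_repression: float = 0.0  # activity units subtracted while intact
    mutation_mean: float = 2.5
    mutation_max: int = 10
    daughters_per_parent: int = 2000
    reads_per_daughter: int = 50
    bin_spillover: float = 0.05
    unsorted_mean: float = 5.0
    # logistic activity parameters; a0=None -> best consensus pair score - 10
    activity_midpoint: float | None = None
    activity_scale: float = 1.5
    pwm_pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.bin_spillover < 0.5:
            raise ValueError("bin_spillover must be in [0, 0.5)")
        if not 1 <= self.mutation_mean <= self.mutation_max:
            raise ValueError("mutation_mean must lie in [1, mutation_max]")


@dataclass
class ActivityModel:
    """Deterministic sequence -> fluorescence map used by the simulator."""

    pwm10: PWM
    pwm35: PWM
    midpoint: float
    scale: float
    hns_site: str | None = None
    hns_repression: float = 0.0
    spacer_min: int = 15
    spacer_max: int = 20

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "ActivityModel":
        pwm10, pwm35 = default_pwms(config.pwm_pseudocount)
        if config.activity_midpoint is None:
            best = pwm10.score(MINUS10_CONSENSUS) + pwm35.score(MINUS35_CONSENSUS)
            midpoint = best - 10.0
        else:
            midpoint = config.activity_midpoint
        return cls(
            pwm10=pwm10,
            pwm35=pwm35,
            midpoint=midpoint,
            scale=config.activity_scale,
            hns_site=config.hns_site,
            hns_repression=config.hns_repression,
        )

    def activity(self, encoded: np.ndarray) -> np.ndarray:
        """Best paired-box score per sequence (0 when no legal pair exists).

        A pair is an above-threshold −35 and −10 hit with a 15-20 bp
        spacer; the activity is the summed score of the best such pair,
        minus the repression strength when an intact planted H-NS site is
        present anywhere in the sequence.
        """
        single = encoded.ndim == 1
        enc = encoded[None, :] if single else encoded
        s10 = self.pwm10.score_positions(enc)
        s35 = self.pwm35.score_positions(enc)
        ok10 = s10 >= self.pwm10.threshold
        ok35 = s35 >= self.pwm35.threshold
        n = enc.shape[0]
        act = np.zeros(n)
        w35 = self.pwm35.width
        for spacer in range(self.spacer_min, self.spacer_max + 1):
            off = w35 + spacer  # start10 - start35
            if off >= s10.shape[1]:
                continue
            pair = np.where(
                ok35[:, : s10.shape[1] - off] & ok10[:, off:],
                s35[:, : s10.shape[1] - off] + s10[:, off:],
                -np.inf,
            ).max(axis=1)
            act = np.maximum(act, np.where(np.isfinite(pair), pair, 0.0))
        if self.hns_site and self.hns_repression:
            site = encode(self.hns_site)
            win = np.lib.stride_tricks.sliding_window_view(enc, len(site), axis=1)
            intact = (win == site).all(axis=2).any(axis=1)
            act = np.where(intact, act - self.hns_repression, act)
        return act[0] if single else act

    def fluorescence(self, encoded: np.ndarray) -> np.ndarray:
        """F = 1 + 3 / (1 + exp(-(a - a0)/s)), in [1, 4]."""
        a = self.activity(encoded)
        return 1.0 + 3.0 / (1.0 + np.exp(-(a - self.midpoint) / self.scale))


def latent_fluorescence(seq: str, config: SimulationConfig | None = None,
                        model: ActivityModel | None = None) -> tuple[float, float]:
    """Deterministic latent (F_top, F_bottom) for one sequence.

    F_top is read by GFP on the given strand; F_bottom by RFP on the
    reverse complement.
    """
    if model is None:
        model = ActivityModel.from_config(config or SimulationConfig())
    f_top = float(model.fluorescence(encode(seq)))
    f_bottom = float(model.fluorescence(encode(revcomp(seq))))
    return f_top, f_bottom


# ---------------------------------------------------------------------------
# parent generation

def _random_background(length: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def generate_parent(
    config: SimulationConfig, rng, template_index: int = 0, max_tries: int = 200
) -> tuple[str, dict]:
    """One template sequence plus its ground-truth entry.

    Plants the consensus −35/−10 pair at a random feasible offset (top
    strand), writes decoy boxes (alternating classes) at non-overlapping
    random positions, and optionally a H-NS site. For non-promoter
    templates (``plant_promoter=False``) generation retries until no legal
    above-threshold pair exists on the top strand.
    """
    rng = np.random.default_rng(rng)
    model = ActivityModel.from_config(config)
    L = config.seq_length
    for _ in range(max_tries):
        enc = _random_background(L, config.gc_content, rng)
        occupied: list[tuple[int, int]] = []
        placed: list[tuple[str, int]] = []  # (motif class, start)
        truth: dict = {"template_index": template_index, "strand": "top"}

        def place(motif: str, start: int, allow_pairing: bool = True) -> bool:
            iv = (start, start + len(motif))
            if any(s < iv[1] and iv[0] < e for s, e in occupied):
                return False
            if not allow_pairing and motif in (MINUS10_CONSENSUS, MINUS35_CONSENSUS):
                # a decoy must not complete a legally spaced pair
                for other, o_start in placed:
                    if other == motif:
                        continue
                    s35, s10 = (start, o_start) if motif == MINUS35_CONSENSUS else (o_start, start)
                    if 15 <= s10 - (s35 + 6) <= 20:
                        return False
            enc[iv[0] : iv[1]] = encode(motif)
            occupied.append(iv)
            placed.append((motif, start))
            return True

        ok = True
        if config.plant_promoter:
            spacer = config.spacer if config.spacer is not None else int(rng.integers(15, 21))
            span = 6 + spacer + 6
            m35 = int(rng.integers(15, L - span - 15))
            m10 = m35 + 6 + spacer
            ok = place(MINUS35_CONSENSUS, m35) and place(MINUS10_CONSENSUS, m10)
            truth.update({"minus35_start": m35, "minus10_start": m10, "spacer": spacer})
        if ok and config.hns_site:
            for _ in range(50):
                s = int(rng.integers(0, L - len(config.hns_site)))
                if place(config.hns_site, s):
                    truth["hns_start"] = s
                    break
            else:
                ok = False
        if ok:
            decoys = []
            for d in range(config.n_decoys):
                motif = MINUS10_CONSENSUS if d % 2 == 0 else MINUS35_CONSENSUS
                for _ in range(50):
                    s = int(rng.integers(0, L - 6))
                    if place(motif, s, allow_pairing=False):
                        decoys.append({"motif": motif, "start": s})
                        break
                else:
                    ok = False
            truth["decoys"] = decoys
        if not ok:
            continue
        seq = "".join(BASES[i] for i in enc)
        act = float(model.activity(encode(seq)))
        if config.plant_promoter:
            # the planted pair, not a chance background pair, must carry the activity
            if act < model.midpoint + 5.0:
                continue
        elif act > 0:
            continue  # accidental legal pair; resample background
        truth["latent_F_top"] = float(model.fluorescence(encode(seq)))
        return seq, truth
    raise RuntimeError("could not place planted elements; loosen the configuration")


def _truncated_poisson_lambda(mean: float) -> float:
    """lambda with zero-truncated Poisson mean equal to *mean*."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 10.0 * mean)


def mutate_daughters(parent: str, n: int, config: SimulationConfig, rng) -> list[str]:
    """Point-mutant daughters of *parent*.

    Mutation counts are zero-truncated Poisson with truncated mean
    ``mutation_mean``, capped at ``mutation_max``; positions are drawn
    without replacement and each substitution is uniform over the three
    alternative bases.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    lam = _truncated_poisson_lambda(config.mutation_mean)
    counts = rng.poisson(lam, size=n)
    while (counts == 0).any():
        zeros = counts == 0
        counts[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    counts = np.minimum(counts, config.mutation_max)
    enc = encode(parent)
    daughters = []
    for k in counts:
        d = enc.copy()
        pos = rng.choice(len(parent), size=int(k), replace=False)
        # uniform over the 3 non-identical bases
        d[pos] = (d[pos] + rng.integers(1, 4, size=int(k))) % 4
        daughters.append("".join(BASES[i] for i in d))
    return daughters


def simulate_bin_reads(F: float, depth: int, epsilon: float, rng) -> np.ndarray:
    """Multinomial read counts over bins 1..4 for one latent score.

    The true bin is round-half-up(F); probability 1-2*epsilon stays there
    and epsilon leaks to each existing adjacent bin (edge bins
    renormalize over the available mass).
    """
    rng = np.random.default_rng(rng)
    return _bin_reads_many(np.asarray([F], dtype=float), depth, epsilon, rng)[0]


def _bin_probs(F: np.ndarray, epsilon: float) -> np.ndarray:
    true_bin = np.clip(np.floor(F + 0.5).astype(int), 1, 4) - 1
    probs = np.zeros((F.size, 4))
    rows = np.arange(F.size)
    probs[rows, true_bin] = 1.0 - 2.0 * epsilon
    for shift in (-1, 1):
        nb = true_bin + shift
        okm = (nb >= 0) & (nb <= 3)
        probs[rows[okm], nb[okm]] += epsilon
    return probs / probs.sum(axis=1, keepdims=True)


def _bin_reads_many(F: np.ndarray, depth: int, epsilon: float, rng) -> np.ndarray:
    return rng.multinomial(depth, _bin_probs(F, epsilon))


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class SimulatedDataset:
    parents: list[ParentSequence]
    table: pd.DataFrame  # sortseq_io daughter-table dialect + parent_id
    truth: dict  # per-parent planted coordinates, model params, latent F


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic experiment: parents, daughters, noisy bin counts, truth."""
    rng = np.random.default_rng(config.seed)
    model = ActivityModel.from_config(config)
    parents = []
    rows = []
    truth: dict = {
        "config": {
            "n_templates": config.n_templates,
            "daughters_per_parent": config.daughters_per_parent,
            "reads_per_daughter": config.reads_per_daughter,
            "bin_spillover": config.bin_spillover,
            "mutation_mean": config.mutation_mean,
            "seed": config.seed,
        },
        "activity": {"midpoint": model.midpoint, "scale": model.scale},
        "parents": {},
    }
    for t in range(config.n_templates):
        pid = f"P{t + 1}"
        seq, ptruth = generate_parent(config, rng, template_index=t)
        parents.append(ParentSequence(pid, seq))
        daughters = mutate_daughters(seq, config.daughters_per_parent, config, rng)
        enc = encode_many(daughters)
        f_top = model.fluorescence(enc)
        enc_rc = encode_many([revcomp(d) for d in daughters])
        f_bottom = model.fluorescence(enc_rc)
        gfp = _bin_reads_many(f_top, config.reads_per_daughter, config.bin_spillover, rng)
        rfp = _bin_reads_many(f_bottom, config.reads_per_daughter, config.bin_spillover, rng)
        unsorted = 1 + rng.poisson(config.unsorted_mean, size=len(daughters))
        for j, d in enumerate(daughters):
            rows.append(
                {
                    "sequence": d,
                    "parent_id": pid,
                    "gfp_bin1": gfp[j, 0], "gfp_bin2": gfp[j, 1],
                    "gfp_bin3": gfp[j, 2], "gfp_bin4": gfp[j, 3],
                    "rfp_bin1": rfp[j, 0], "rfp_bin2": rfp[j, 1],
                    "rfp_bin3": rfp[j, 2], "rfp_bin4": rfp[j, 3],
                    "unsorted_reads": unsorted[j],
                }
            )
        ptruth["latent_F_gfp"] = f_top.tolist()
        ptruth["latent_F_rfp"] = f_bottom.tolist()
        truth["parents"][pid] = ptruth
    table = pd.DataFrame(rows, columns=["sequence", "parent_id", *COUNT_COLUMNS])
    return SimulatedDataset(parents=parents, table=table, truth=truth)


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Emit parents FASTA, daughter-table CSV, and truth JSON.

    Round-trips losslessly through sortseq_io readers; byte-deterministic
    for a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "parents": out / "parents.fasta",
        "table": out / "daughters.csv",
        "truth": out / "truth.json",
    }
    write_parents_fasta(dataset.parents, paths["parents"])
    dataset.table.to_csv(paths["table"], index=False)
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    return paths
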