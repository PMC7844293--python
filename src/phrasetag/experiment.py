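"""Orchestration of the full simulated experiment.

Pipeline: synthetic lexicon -> condition streams (AN, AV, MP, RR plus the
shuffled reference) -> fictive EEG per simulated participant -> onset
trimming -> DFT phases -> ITPC per participant x condition -> random-phase
null and Mann-Whitney peak tests -> phi regularity table.  Every stage
seeds its RNG from a spawned child of the global seed, so a run is fully
reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design
from .errors import PhraseTagError
from .fictive import FictiveEEGParams, shuffle_stream, simulate_participant
from .itpc import (ITPCSpectrum, PhaseRecord, dft_phases, grand_average,
                   itpc_by_participant_condition)
from .lexicon import Category, retain_similar_pairs
from .preprocess import epoch_and_trim, lowpass_filter
from .regularity import normalized_condition_phi, phi_statistic
from .stats import NullDistribution, peak_significance, simulate_null_itpc
from .streams import (Condition, Stream, build_alternating_stream,
                      build_mp_stream, build_rr_stream)
from .synthetic import SyntheticLexiconSpec, generate_category_lexicon

log = logging.getLogger("phrasetag")

#: conditions simulated as fictive EEG (SHUF is the shuffled-RR reference)
SIMULATED_CONDITIONS = (Condition.AN, Condition.AV, Condition.MP, Condition.SHUF)


@dataclass
class RunConfig:
    """Defaults reproduce the study design: 52-word streams of 320 ms words,
    24 analysed streams per condition, 20 participants, 32 of 300 electrode
    components, 5000 null replicates, analysis bins 24 (phrase) and 48
    (syllable)."""

    seed: int = 0
    n_streams: int = 24
    n_participants: int = 20
    fictive: FictiveEEGParams = field(default_factory=FictiveEEGParams)
    lexicon: SyntheticLexiconSpec = field(default_factory=SyntheticLexiconSpec)
    analysis_bins: tuple[int, int] = (design.PHRASE_BIN, design.SYLLABLE_BIN)
    spectrum_max_bin: int = 192          # 12.5 Hz at 0.0651 Hz resolution
    null_n_rep: int = 5000
    sim_window: tuple[float, float] = (0.75, 1.0)
    lowpass_hz: float | None = None      # fictive data: trim only by default
    alpha: float = 0.05

    def __post_init__(self):
        design.assert_tag_bins_on_grid()
        if self.lexicon.dim != self.fictive.n_components:
            raise PhraseTagError(
                f"lexicon dim {self.lexicon.dim} != fictive components {self.fictive.n_components}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lexicon"]["categories"] = [c.value for c in self.lexicon.categories]
        d["lexicon"]["designated_pairs"] = [
            [a.value, b.value] for a, b in self.lexicon.designated_pairs
        ]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fictive" in raw:
            raw["fictive"] = FictiveEEGParams(**{
                k: tuple(v) if k == "tau_range" else v for k, v in raw["fictive"].items()
            })
        if "lexicon" in raw:
            lx = dict(raw["lexicon"])
            if "categories" in lx:
                lx["categories"] = tuple(Category(c) for c in lx["categories"])
            if "designated_pairs" in lx:
                lx["designated_pairs"] = tuple(
                    (Category(a), Category(b)) for a, b in lx["designated_pairs"]
                )
            for k in ("target_cross_similarity",):
                if k in lx:
                    lx[k] = tuple(lx[k])
            raw["lexicon"] = SyntheticLexiconSpec(**lx)
        for k in ("analysis_bins", "sim_window"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class ExperimentReport:
    """All tables produced by one simulated experiment."""

    grand_average: pd.DataFrame      # condition, bin, freq_hz, itpc
    participant_curves: pd.DataFrame  # participant, condition, bin, freq_hz, itpc
    significance: pd.DataFrame       # condition, bin, freq_hz, p_value, significant
    phi: pd.DataFrame                # condition, mean_phi, normalized_phi
    null_summary: dict
    config: dict
    config_hash: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = {"config_hash": self.config_hash, "seed": self.config["seed"]}
        for name, df in [
            ("grand_average", self.grand_average),
            ("participant_curves", self.participant_curves),
            ("significance", self.significance),
            ("phi", self.phi),
        ]:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "null_summary.json").write_text(json.dumps({**header, **self.null_summary}, indent=1))
        (out / "config.yaml").write_text(yaml.safe_dump({**self.config, **header}, sort_keys=True))


def build_condition_streams(config: RunConfig, lexicon) -> dict[Condition, list[Stream]]:
    """The four experimental stream sets plus the shuffled reference."""
    ss = np.random.SeedSequence(config.seed).spawn(5)
    seeds = [np.random.default_rng(s).integers(2**31, size=config.n_streams) for s in ss]
    lo, hi = config.sim_window
    an_pairs = retain_similar_pairs(lexicon, Category.ADJ, Category.NOUN, lo, hi)
    av_pairs = retain_similar_pairs(lexicon, Category.ADJ, Category.VERB, lo, hi)
    streams: dict[Condition, list[Stream]] = {c: [] for c in Condition}
    for i in range(config.n_streams):
        streams[Condition.AN].append(
            build_alternating_stream(an_pairs, seed=int(seeds[0][i]), stream_id=f"AN{i:02d}")
        )
        streams[Condition.AV].append(
            build_alternating_stream(av_pairs, seed=int(seeds[1][i]),
                                     condition=Condition.AV, stream_id=f"AV{i:02d}")
        )
        streams[Condition.MP].append(
            build_mp_stream(lexicon, seed=int(seeds[2][i]), stream_id=f"MP{i:02d}")
        )
        rr = build_rr_stream(lexicon, seed=int(seeds[3][i]), stream_id=f"RR{i:02d}")
        streams[Condition.RR].append(rr)
        streams[Condition.SHUF].append(shuffle_stream(rr, seed=int(seeds[4][i])))
    return streams


def run_simulated_experiment(config: RunConfig = RunConfig()) -> ExperimentReport:
    """Execute the whole simulated experiment and return its report."""
    stage = "lexicon"
    try:
        root = np.random.SeedSequence(config.seed)
        ss_lex, ss_streams, ss_parts, ss_null = root.spawn(4)
        log.info("stage=lexicon seed=%d", config.seed)
        lex_spec = SyntheticLexiconSpec(
            **{**asdict(config.lexicon),
               "categories": config.lexicon.categories,
               "designated_pairs": config.lexicon.designated_pairs,
               "seed": int(np.random.default_rng(ss_lex).integers(2**31))}
        )
        lexicon = generate_category_lexicon(lex_spec)

        stage = "streams"
        log.info("stage=streams")
        streams = build_condition_streams(
            _with_seed(config, int(np.random.default_rng(ss_streams).integers(2**31))), lexicon
        )

        stage = "simulate/analyze"
        bins = np.arange(1, config.spectrum_max_bin + 1)
        part_seeds = np.random.default_rng(ss_parts).integers(2**31, size=config.n_participants)
        records: list[PhaseRecord] = []
        for p in range(config.n_participants):
            pid = f"p{p:02d}"
            log.info("stage=simulate participant=%s seed=%d", pid, int(part_seeds[p]))
            for cond in SIMULATED_CONDITIONS:
                epochs = simulate_participant(
                    streams[cond], config.fictive,
                    participant_seed=int(part_seeds[p]) + _condition_offset(cond),
                    participant_id=pid,
                )
                for ep in epochs:
                    ep2 = lowpass_filter(ep, config.lowpass_hz) if config.lowpass_hz else ep
                    ep2 = epoch_and_trim(ep2)
                    records.append(
                        PhaseRecord(pid, cond.value, ep.meta["stream_id"], dft_phases(ep2, bins=bins))
                    )

        stage = "itpc"
        spectrum = itpc_by_participant_condition(records, bins=bins)
        ga = grand_average(spectrum)

        stage = "null/stats"
        null = simulate_null_itpc(
            K=config.n_streams, n_electrodes=config.fictive.n_electrodes,
            n_rep=config.null_n_rep,
            seed=int(np.random.default_rng(ss_null).integers(2**31)),
        )
        sig_rows = []
        for cond in SIMULATED_CONDITIONS:
            for b in config.analysis_bins:
                obs = spectrum.table.query("condition == @cond.value and bin == @b")["itpc"].to_numpy()
                p_val = peak_significance(obs, null)
                sig_rows.append(
                    (cond.value, int(b), design.bin_frequency_hz(b), p_val, p_val < config.alpha)
                )
        significance = pd.DataFrame(
            sig_rows, columns=["condition", "bin", "freq_hz", "p_value", "significant"]
        )

        stage = "phi"
        phi_by_cond = {
            c.value: [phi_statistic(s.vectors()) for s in streams[c]] for c in Condition
        }
        reg = normalized_condition_phi(phi_by_cond, reference=Condition.SHUF.value)
        phi_table = pd.DataFrame(
            [(c, reg.condition_means[c], reg.normalized[c]) for c in sorted(reg.condition_means)],
            columns=["condition", "mean_phi", "normalized_phi"],
        )

        ci = null.confidence_interval(0.95)
        return ExperimentReport(
            grand_average=ga,
            participant_curves=spectrum.table,
            significance=significance,
            phi=phi_table,
            null_summary={
                "null_mean": null.mean(), "ci_low": ci[0], "ci_high": ci[1],
                "K": null.K, "n_electrodes": null.n_electrodes, "n_rep": null.n_rep,
            },
            config=config.to_dict(),
            config_hash=config.config_hash(),
        )
    except PhraseTagError as e:
        raise PhraseTagError(f"stage {stage!r} failed (seed {config.seed}): {e}") from e


def _with_seed(config: RunConfig, seed: int) -> RunConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


def _condition_offset(cond: Condition) -> int:
    # distinct, stable noise seeds per condition within a participant
    return list(Condition).index(cond) * 1_000_003
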