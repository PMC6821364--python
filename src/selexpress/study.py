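"""Reference simulation studies exercising the pipeline end to end.

Each function runs one canonical study at its documented conditions and
returns the measured quantities.  The studies double as the package's
self-validation: planted-truth recovery for the enrichment/PWM stage, null
calibration of the enrichment statistic, parameter recovery for the Hill
stage, the occupancy-model ordering of fitted Vmax, and planted-signal
recovery for the sequence model and feature importance.  Problem sizes are
chosen to run on a single CPU in minutes; docs/methods.md discusses what
they do and do not establish.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.stats import spearmanr

from . import simulate as sim
from .enrichment import MotifEnrichmentModel
from .importance import AnnealSchedule, FeatureImportanceModel
from .induction import fit_hill, hill_curve
from .kmers import count_patterns, enrichment_table, MarkovBackground


def _sub(seed: int, k: int) -> int:
    return (int(seed) * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# planted-motif recovery


def seed_matches_core(seed_text: str, core_text: str) -> int | None:
    """Alignment offset at which every non-wildcard seed position agrees
    with the planted core consensus, or None if no such offset exists."""
    span = len(seed_text)
    for off in range(0, len(core_text) - span + 1):
        ok = True
        for i, c in enumerate(seed_text):
            if c == "x":
                continue
            if core_text[off + i] != c:
                ok = False
                break
        if ok:
            return off
    return None


def planted_full_matrix(motif: sim.PlantedMotif) -> np.ndarray:
    return np.vstack(
        [motif.left_pwm, np.full((motif.spacer, 4), 0.25), motif.right_pwm]
    )


def motif_recovery_study(
    seed: int = 1,
    library_reads: int = 5_000_000,
    reads_per_round: int = 50_000,
    rounds: int = 5,
    beta: float = 2.0,
) -> dict:
    """Five selection rounds against the planted palindromic dimer, then the
    full enrichment -> seed -> PWM analysis.  Measures whether the
    top-enriched gapped k-mer matches the planted core and how well the PWM
    columns correlate with the planted half-site PWMs."""
    bg = sim.biased_background(sim.SELECTION_BASE_FREQS, persistence=0.1)
    lib = sim.generate_background_library(bg, n_reads=library_reads, seed=_sub(seed, 1))
    motif = sim.default_planted_motif()
    cfg = sim.SelectionSimConfig(
        true_motif=motif,
        reads_per_round=reads_per_round,
        rounds=rounds,
        stringency=beta,
        seed=_sub(seed, 2),
    )
    pools = sim.simulate_selection(lib, cfg)
    final = pools[-1]
    res = MotifEnrichmentModel(final, background_reads=lib).fit()

    core = motif.core_pattern
    offset = seed_matches_core(res.seed.text, core)
    min_corr = float("nan")
    if offset is not None:
        full = planted_full_matrix(motif)
        corrs = []
        for i in range(len(res.pwm)):
            if res.pwm.wildcard_mask[i]:
                continue
            a, b = res.pwm.probs[i], full[offset + i]
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
        min_corr = min(corrs)

    # enrichment of core-containing reads, round 0 vs final round
    import re

    pat = re.compile(core.replace("x", "."))
    probe = lib[: min(len(lib), 500_000)]
    f0 = sum(bool(pat.search(s)) for s in probe) / len(probe)
    f_final = sum(c for s, c in final.items() if pat.search(s)) / sum(final.values())
    return {
        "core_recovered": offset is not None,
        "seed_text": res.seed.text,
        "core_text": core,
        "min_column_correlation": min_corr,
        "core_frequency_gain": f_final / max(f0, 1e-12),
        "results": res,
        "final_pool": final,
    }


# ---------------------------------------------------------------------------
# null calibration


def null_calibration_study(
    seed: int = 1,
    library_reads: int = 2_000_000,
    sample_reads: int = 100_000,
    band: tuple[float, float] = (0.8, 1.25),
) -> dict:
    """One beta=0 round sampled from a deeply sequenced biased library; the
    fraction of count-filtered gapped k-mers whose enrichment (per-read-
    any-offset expectation) falls inside the calibration band."""
    bg = sim.biased_background()
    lib = sim.generate_background_library(bg, n_reads=library_reads, seed=_sub(seed, 3))
    cfg = sim.SelectionSimConfig(
        stringency=0.0, rounds=1, reads_per_round=sample_reads, seed=_sub(seed, 4)
    )
    sample = sim.simulate_selection(lib, cfg)[-1]
    model = MarkovBackground.train(lib)
    counts = count_patterns(sample, count_threshold=50)
    lc: Counter = Counter()
    for s, c in sample.items():
        lc[len(s)] += c
    tab = enrichment_table(counts, model, dict(lc), convention="per-read-any-offset")
    e = tab["enrichment"].to_numpy()
    return {
        "fraction_in_band": float(((e >= band[0]) & (e <= band[1])).mean()),
        "n_patterns": len(e),
        "table": tab,
    }


# ---------------------------------------------------------------------------
# Hill parameter recovery


def hill_recovery_study(
    seed: int = 1,
    n_seeds: int = 100,
    noise_cv: float = 0.05,
    replicates: int = 3,
    true_params: dict | None = None,
) -> dict:
    """Dose series at 8 concentrations x replicates with multiplicative
    noise; median absolute parameter-recovery errors across seeds, plus the
    worst-case relative error on noiseless data."""
    p = true_params or dict(y0=5.0, vmax=100.0, km=50.0, n=2.0)
    L = np.tile([0.0, 0.5, 2.0, 8.0, 30.0, 100.0, 400.0, 1500.0], replicates)
    clean = hill_curve(L, p["y0"], p["vmax"], p["km"], p["n"])

    res0 = fit_hill(L, clean)
    noiseless_err = max(
        abs(res0.y0 - p["y0"]) / p["y0"],
        abs(res0.vmax - p["vmax"]) / p["vmax"],
        abs(res0.km - p["km"]) / p["km"],
        abs(res0.hill_n - p["n"]) / p["n"],
    )

    km_err, vmax_err, n_err = [], [], []
    base = np.random.SeedSequence(_sub(seed, 5))
    for child in base.spawn(n_seeds):
        r = np.random.default_rng(child)
        y = clean * r.lognormal(-0.5 * np.log1p(noise_cv**2), np.sqrt(np.log1p(noise_cv**2)), L.size)
        res = fit_hill(L, y)
        km_err.append(abs(res.km - p["km"]) / p["km"])
        vmax_err.append(abs(res.vmax - p["vmax"]) / p["vmax"])
        n_err.append(abs(res.hill_n - p["n"]))
    return {
        "noiseless_max_rel_error": float(noiseless_err),
        "km_median_rel_error": float(np.median(km_err)),
        "vmax_median_rel_error": float(np.median(vmax_err)),
        "n_median_abs_error": float(np.median(n_err)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# occupancy-mechanism ordering


def affinity_vmax_study(seed: int = 1, kd_grid=(3.0, 10.0, 30.0, 100.0, 300.0)) -> dict:
    """Simulate dose responses across an operator-Kd grid (repressor in
    excess, small residual holo-repressor activity) and fit Hill curves.
    Measures the rank correlation of Kd with fitted Vmax and with fold
    repression: tighter operators keep more residual binding when induced
    (lower Vmax) and repress more deeply."""
    cfg = sim.ExpressionSimConfig(
        atf_level=10_000.0,
        ligand_kd=1.0,
        v_const=100.0,
        noise_cv=0.05,
        residual_activity=3e-3,
        seed=_sub(seed, 6),
    )
    kds = {f"op{int(kd)}": kd for kd in kd_grid}
    concs = np.r_[0.0, np.geomspace(0.03, 3000.0, 9)]
    df = sim.simulate_expression(kds, concs, cfg, replicates=3)
    vmaxes, y0s = [], []
    for clone in kds:
        grp = df[df["clone_id"] == clone]
        res = fit_hill(
            grp["ligand_conc"].to_numpy(), (grp["gfp_raw"] / grp["od600"]).to_numpy()
        )
        vmaxes.append(res.vmax)
        y0s.append(res.y0)
    fr = [cfg.v_const / max(y, 1e-9) for y in y0s]
    return {
        "spearman_kd_vmax": float(spearmanr(list(kd_grid), vmaxes).statistic),
        "spearman_kd_fold_repression": float(spearmanr(list(kd_grid), fr).statistic),
        "vmax": vmaxes,
        "fold_repression": fr,
    }


# ---------------------------------------------------------------------------
# sequence model on labeled operators


def sequence_model_study(seed: int = 1, n_per_class: int = 100) -> dict:
    """Out-of-fold and holdout Spearman correlation of the SVR on the
    planted-signal labeled operator sets (n ~ 2 * n_per_class)."""
    ops = sim.generate_labeled_operator_sets(n_per_class=n_per_class, seed=_sub(seed, 7))
    from .regression import InductionRegressionModel

    res = InductionRegressionModel(ops["sequence"], ops["fold_induction"]).fit(
        seed=_sub(seed, 8) % 10_000
    )
    return {
        "oof_spearman": res.cv_metrics["spearman"],
        "oof_pearson": res.cv_metrics["pearson"],
        "holdout_spearman": res.holdout_metrics["spearman"],
        "n_sequences": len(ops),
        "results": res,
    }


# ---------------------------------------------------------------------------
# feature-importance recovery

PLANTED_POSITIONS = frozenset(range(6)) | {6, 12}  # core windows 0-3/2-5 + flanks
CORE_POSITIONS = frozenset(range(6))
FLANK_POSITIONS = frozenset({6, 12})


def importance_recovery_study(
    seed: int = 1,
    n_outer: int = 10,
    n_bootstrap: int = 100,
    n_per_class: int = 30,
    anneal_iters: int = 60,
    top_k: int = 6,
) -> dict:
    """For each outer seed: fresh labeled operator set, bootstrap annealing
    importance, and a check that the top differential (position, character)
    scores all sit on planted positions, touching both the shifted core
    window and the planted flanks.  Returns the success fraction."""
    successes = 0
    details = []
    for k in range(n_outer):
        ops = sim.generate_labeled_operator_sets(
            n_per_class=n_per_class, seed=_sub(seed, 10 + k)
        )
        model = FeatureImportanceModel(ops["sequence"], ops["fold_induction"])
        res = model.fit(
            n_bootstrap=n_bootstrap,
            schedule=AnnealSchedule(n_iter=anneal_iters),
            seed=_sub(seed, 50 + k),
        )
        top = res.matrix.differential().head(top_k)
        pos = set(top["position"])
        ok = (
            pos.issubset(PLANTED_POSITIONS)
            and bool(pos & CORE_POSITIONS)
            and bool(pos & FLANK_POSITIONS)
        )
        successes += ok
        details.append({"positions": sorted(pos), "ok": ok})
    return {
        "success_fraction": successes / n_outer,
        "n_outer": n_outer,
        "details": details,
    }


__all__ = [
    "affinity_vmax_study",
    "hill_recovery_study",
    "importance_recovery_study",
    "motif_recovery_study",
    "null_calibration_study",
    "planted_full_matrix",
    "seed_matches_core",
    "sequence_model_study",
]
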