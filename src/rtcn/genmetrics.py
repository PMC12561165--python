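"""Quality metrics for diffusion-generated heartbeats.

* FID — Fréchet distance between Gaussian fits of real vs generated feature
  distributions: ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^(1/2)).
* CRPS — continuous ranked probability score of the synthetic ensemble's
  empirical CDF against each real trace, via the exact discrete identity
  E|X - y| - (1/2) E|X - X'| averaged over time points and test beats.
* DTW — dynamic-time-warping alignment cost (absolute local cost; match /
  insert / delete steps) between same-class real–synthetic pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


def fid(real_features: np.ndarray, gen_features: np.ndarray,
        eps: float = 1e-9) -> float:
    """Fréchet distance between Gaussian fits of two feature samples."""
    r = np.atleast_2d(np.asarray(real_features, dtype=float))
    g = np.atleast_2d(np.asarray(gen_features, dtype=float))
    if r.shape[1] != g.shape[1]:
        raise ValueError("feature dimensions differ")
    if r.shape[0] < 2 or g.shape[0] < 2:
        raise ValueError("need at least two samples per side")
    mu_r, mu_g = r.mean(axis=0), g.mean(axis=0)
    cov_r = np.atleast_2d(np.cov(r, rowvar=False))
    cov_g = np.atleast_2d(np.cov(g, rowvar=False))
    jitter = eps * np.eye(cov_r.shape[0])
    covmean = linalg.sqrtm((cov_r + jitter) @ (cov_g + jitter))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    val = float(np.sum((mu_r - mu_g) ** 2)
                + np.trace(cov_r + cov_g - 2.0 * covmean))
    return max(val, 0.0)


def crps(ensemble: np.ndarray, truth: np.ndarray) -> float:
    """Mean CRPS of the ensemble's empirical CDF over all time points."""
    x = np.atleast_2d(np.asarray(ensemble, dtype=float))   # (m, T)
    y = np.asarray(truth, dtype=float).ravel()
    if x.shape[1] != y.size:
        raise ValueError("ensemble and truth lengths differ")
    if x.shape[0] < 1:
        raise ValueError("need at least one ensemble member")
    term1 = np.mean(np.abs(x - y[None, :]))
    term2 = 0.5 * np.mean(np.abs(x[:, None, :] - x[None, :, :]))
    return float(term1 - term2)


def dtw(a: np.ndarray, b: np.ndarray, band: int | None = None) -> float:
    """Minimal cumulative |a_i - b_j| alignment cost (match/insert/delete).

    ``band`` optionally restricts |i - j| to a Sakoe–Chiba window for speed.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sequence")
    n, m = a.size, b.size
    inf = np.inf
    prev = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, inf)
        lo = 1 if band is None else max(1, i - band)
        hi = m if band is None else min(m, i + band)
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            cost = abs(ai - b[j - 1])
            cur[j] = cost + min(prev[j - 1], prev[j], cur[j - 1])
        prev = cur
    return float(prev[m])


def downsample_features(beats: np.ndarray, factor: int = 8) -> np.ndarray:
    """Plain decimation feature map — the cheap default FID extractor."""
    return np.atleast_2d(np.asarray(beats, dtype=float))[:, ::factor]


def backbone_feature_extractor(model, side: int | None = None):
    """FID features from a trained backbone truncated at global pooling.

    Returns a callable mapping a (n, 3, side, side) image stack to pooled
    backbone features.
    """
    def extract(images):
        model.eval()
        feats = []
        for i in range(0, len(images), 16):
            f = model.backbone(np.asarray(images[i : i + 16], dtype=float))
            feats.append(f.mean(axis=(2, 3)))
        return np.concatenate(feats, axis=0)
    return extract


@dataclass
class GenQualityReport:
    per_class: dict                       # label -> metric dict
    missing_classes: list = field(default_factory=list)
    n_real: int = 0
    n_synthetic: int = 0

    def summary(self) -> str:
        lines = [f"{'Class':<8}{'FID':>10}{'CRPS':>16}{'DTW':>16}"]
        for label, row in self.per_class.items():
            lines.append(
                f"{label:<8}{row['fid']:>10.3f}"
                f"{row['crps']:>9.4f} ±{row['crps_std']:.4f}"
                f"{row['dtw']:>9.2f} ±{row['dtw_std']:.2f}")
        if self.missing_classes:
            lines.append(f"missing on one side: {', '.join(self.missing_classes)}")
        return "\n".join(lines)


def quality_report(real_beats, synthetic_beats, feature_extractor=None,
                   seed: int = 0, crps_ensemble: int = 50, max_pairs: int = 8,
                   dtw_band: int | None = 50, n_bootstrap: int = 20) -> GenQualityReport:
    """Per-class FID / mean CRPS / mean DTW between real and synthetic beats.

    Classes present on only one side are reported as missing, not an error.
    Dispersion is a bootstrap std over resampled pairings.
    """
    rng = np.random.default_rng(seed)
    extractor = feature_extractor or downsample_features

    def group(beats):
        out: dict = {}
        for b in beats:
            out.setdefault(b.label, []).append(np.asarray(b.samples, dtype=float))
        return {k: np.stack(v) for k, v in out.items()}

    real, synth = group(real_beats), group(synthetic_beats)
    shared = sorted(set(real) & set(synth))
    missing = sorted(set(real) ^ set(synth))

    per_class = {}
    for label in shared:
        r, s = real[label], synth[label]
        fid_val = fid(extractor(r), extractor(s)) if min(len(r), len(s)) >= 2 \
            else float("nan")
        # CRPS: ensemble of synthetic beats against each real trace
        ens_idx = rng.choice(len(s), size=min(crps_ensemble, len(s)), replace=False)
        ens = s[ens_idx]
        crps_vals = np.array([crps(ens, y) for y in r[: max(2 * max_pairs, 4)]])
        # DTW: seeded random same-class pairing
        n_pairs = min(len(r), len(s), max_pairs)
        ri = rng.choice(len(r), size=n_pairs, replace=False)
        si = rng.choice(len(s), size=n_pairs, replace=False)
        dtw_vals = np.array([dtw(r[i], s[j], band=dtw_band)
                             for i, j in zip(ri, si)])
        boot = [np.mean(rng.choice(dtw_vals, size=dtw_vals.size, replace=True))
                for _ in range(n_bootstrap)]
        per_class[label] = {
            "fid": fid_val,
            "crps": float(crps_vals.mean()),
            "crps_std": float(crps_vals.std()),
            "dtw": float(dtw_vals.mean()),
            "dtw_std": float(np.std(boot)),
        }
    return GenQualityReport(per_class, missing,
                            n_real=sum(len(v) for v in real.values()),
                            n_synthetic=sum(len(v) for v in synth.values()))
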