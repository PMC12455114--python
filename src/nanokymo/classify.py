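"""Conformational classification from the extension-vs-SD scatter.

Lambda-DNA carries complementary 12-base overhangs, so a sample contains
linear monomers, circles (self-hybridized, ~half the apparent contour),
fragments (photo-cleaved pieces), and concatemers (end-joined multimers).
In a nanochannel these populations separate in the plane of time-averaged
extension vs the standard deviation of the extension: the dominant
monomer cluster sits at full extension, fragments and circles at lower
extension and/or SD, concatemers above.

The default classifier is deterministic: locate the monomer cluster as
the 2-D mode of (extension, SD), gate linear monomers within ``k_mad``
robust MADs of the mode on both axes, then assign the remaining points by
extension relative to the mode.  A Gaussian-mixture alternative is
available behind ``method="gmm"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .kymo import MoleculeSummary

logger = logging.getLogger(__name__)

__all__ = ["ClassifiedMolecule", "classify_molecules", "filter_monomers"]

CLASS_LABELS = ("linear-monomer", "circle", "fragment", "concatemer")


@dataclass
class ClassifiedMolecule:
    summary: MoleculeSummary
    class_label: str
    score: float              # membership score in [0, 1]

    @property
    def molecule_id(self) -> int:
        return self.summary.molecule_id


def _robust_mad(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x)))) + 1e-12


def _mode_2d(ext: np.ndarray, sd: np.ndarray) -> tuple[float, float]:
    """2-D mode of the scatter via a Gaussian KDE evaluated at the points."""
    pts = np.vstack([ext, sd])
    scales = pts.std(axis=1)
    if np.any(scales == 0):
        return float(np.median(ext)), float(np.median(sd))
    try:
        dens = gaussian_kde(pts / scales[:, None])(pts / scales[:, None])
        i = int(np.argmax(dens))
        return float(ext[i]), float(sd[i])
    except np.linalg.LinAlgError:
        return float(np.median(ext)), float(np.median(sd))


def classify_molecules(
    summaries: list[MoleculeSummary],
    method: str = "mode-mad",
    k_mad: float = 3.0,
    circle_fraction: tuple[float, float] = (0.5, 0.7),
    min_molecules: int = 20,
) -> list[ClassifiedMolecule]:
    """Assign a conformational class to every molecule summary.

    Gates are derived from the data (mode and MADs), so the labels are
    invariant to a common rescaling of all extensions.  ``circle_fraction``
    is the extension band, relative to the monomer mode, in which a
    low-SD molecule is called a circle rather than a fragment.
    """
    if len(summaries) < min_molecules:
        raise ValueError(
            f"classification needs >= {min_molecules} molecules for robust "
            f"mode estimation (got {len(summaries)}); pool acquisitions"
        )
    ext = np.array([s.extension_um for s in summaries])
    sd = np.array([s.extension_sd_um for s in summaries])

    if method == "gmm":
        return _classify_gmm(summaries, ext, sd)
    if method != "mode-mad":
        raise ValueError(f"unknown method {method!r}")

    mode_ext, mode_sd = _mode_2d(ext, sd)
    # robust spread from the core of the monomer cluster only
    core = (np.abs(ext - mode_ext) < 0.15 * mode_ext)
    if core.sum() < 5:
        core = np.ones_like(ext, dtype=bool)
    mad_ext = _robust_mad(ext[core])
    mad_sd = _robust_mad(sd[core])
    sd_median_core = float(np.median(sd[core]))

    out: list[ClassifiedMolecule] = []
    lo_gate = mode_ext - k_mad * mad_ext
    hi_gate = mode_ext + k_mad * mad_ext
    for s, e, v in zip(summaries, ext, sd):
        z_e = (e - mode_ext) / mad_ext
        z_v = (v - mode_sd) / mad_sd
        score = float(np.exp(-0.5 * z_e**2) * np.exp(-0.5 * z_v**2))
        if lo_gate <= e <= hi_gate and abs(z_v) <= k_mad:
            label = "linear-monomer"
        elif e > hi_gate:
            label = "concatemer"
        else:
            frac = e / mode_ext
            if circle_fraction[0] <= frac <= circle_fraction[1] and v < sd_median_core:
                label = "circle"
            else:
                label = "fragment"
        out.append(ClassifiedMolecule(summary=s, class_label=label, score=score))
    return out


def _classify_gmm(summaries, ext, sd) -> list[ClassifiedMolecule]:
    """Gaussian-mixture alternative: clusters ranked by extension center."""
    from sklearn.mixture import GaussianMixture

    X = np.column_stack([ext, sd])
    best = None
    for k in (2, 3, 4):
        gm = GaussianMixture(n_components=k, random_state=0, n_init=3).fit(X)
        if best is None or gm.bic(X) < best.bic(X):
            best = gm
    labels_idx = best.predict(X)
    resp = best.predict_proba(X)
    order = np.argsort(best.means_[:, 0])
    counts = np.bincount(labels_idx, minlength=best.n_components)
    main = int(np.argmax(counts))
    name: dict[int, str] = {}
    for comp in range(best.n_components):
        if comp == main:
            name[comp] = "linear-monomer"
        elif best.means_[comp, 0] > best.means_[main, 0]:
            name[comp] = "concatemer"
        elif best.means_[comp, 0] > 0.5 * best.means_[main, 0] \
                and best.means_[comp, 1] < best.means_[main, 1]:
            name[comp] = "circle"
        else:
            name[comp] = "fragment"
    _ = order
    return [
        ClassifiedMolecule(summary=s, class_label=name[li],
                           score=float(resp[i, li]))
        for i, (s, li) in enumerate(zip(summaries, labels_idx))
    ]


def filter_monomers(classified: list[ClassifiedMolecule]) -> list[ClassifiedMolecule]:
    """Keep only full-length linear monomers, preserving order.

    Downstream extension/intensity statistics are computed on this subset
    so that populations remain comparable across conditions.  Per-class
    counts are logged; an empty result warns.
    """
    counts: dict[str, int] = {}
    for c in classified:
        counts[c.class_label] = counts.get(c.class_label, 0) + 1
    logger.info("class counts: %s", counts)
    out = [c for c in classified if c.class_label == "linear-monomer"]
    if not out:
        logger.warning("no linear monomers after filtering (counts: %s)", counts)
    return out


def scatter_plot(classified: list[ClassifiedMolecule], path) -> None:
    """Extension-vs-SD scatter with marginal histograms, colored by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ext = np.array([c.summary.extension_um for c in classified])
    sd = np.array([c.summary.extension_sd_um for c in classified])
    labels = np.array([c.class_label for c in classified])
    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_hx = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_hy = fig.add_subplot(gs[1, 1], sharey=ax)
    for lab in CLASS_LABELS:
        m = labels == lab
        if m.any():
            ax.scatter(ext[m], sd[m], s=8, label=lab, alpha=0.6)
    ax_hx.hist(ext, bins=40, color="gray")
    ax_hy.hist(sd, bins=40, orientation="horizontal", color="gray")
    ax_hx.tick_params(labelbottom=False)
    ax_hy.tick_params(labelleft=False)
    ax.set_xlabel("extension (um)")
    ax.set_ylabel("extension SD (um)")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
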