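"""Shared fixtures: small rendered scenes and ground-truth matching helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dropgrowth import DropletROI, generate_series


def gt_rois(scene, image_id="img"):
    """Ground-truth ROIs for a synthetic scene (bypasses detection)."""
    return [
        DropletROI(
            id=i,
            center=d.center,
            radius=d.radius,
            image_id=image_id,
        )
        for i, d in enumerate(scene.droplets)
    ]


def match_detections(scene, rois, center_tol_frac=0.3):
    """Match detected ROIs to ground truth; returns (recall, fp_rate, radius_errs).

    A detection matches the nearest unclaimed ground-truth droplet if the
    center distance is below ``center_tol_frac`` of that droplet's radius;
    everything else counts as a false positive.
    """
    gt = [(d.center, d.radius) for d in scene.droplets]
    matched: dict[int, float] = {}
    fp = 0
    radius_errs = []
    for r in rois:
        dists = [np.hypot(r.center[0] - c[0], r.center[1] - c[1]) for c, _ in gt]
        i = int(np.argmin(dists))
        if dists[i] <= center_tol_frac * gt[i][1] and i not in matched:
            matched[i] = dists[i]
            radius_errs.append(abs(r.radius - gt[i][1]) / gt[i][1])
        else:
            fp += 1
    return len(matched) / len(gt), fp / len(gt), radius_errs


@pytest.fixture(scope="session")
def two_timepoint_series():
    """One rendered droplet cohort imaged at 0 h and 48 h.

    λ is raised to 1.0 so the small cohort reliably contains occupied
    droplets; pixel size 1.0 µm/px keeps images small (512²) while radii
    stay above 20 px.
    """
    return generate_series(
        n_droplets=10,
        seed=42,
        timepoints=[0.0, 48.0],
        lambda_=1.0,
        pixel_size=1.0,
        shape=(512, 512),
    )


@pytest.fixture(scope="session")
def dense_scene():
    """A single post-incubation scene where most droplets are occupied."""
    return generate_series(
        n_droplets=12,
        seed=7,
        timepoints=[48.0],
        lambda_=2.0,
        pixel_size=1.0,
        shape=(512, 512),
    )[0]
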