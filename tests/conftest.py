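"""Shared fixtures: a toy atlas, synthetic cohorts, and one trained model.

Everything is generated programmatically with fixed seeds; the trained
classifier is session-scoped because fitting it dominates the suite's
runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import petslice as ps

DIMS = (24, 28, 24)
HYPO = [1, 2]
HYPER = [3]


@pytest.fixture(scope="session")
def toy_atlas():
    return ps.generate_toy_atlas(DIMS, 6, seed=0)


@pytest.fixture(scope="session")
def fdg_cohort(toy_atlas):
    cfg = ps.SyntheticCohortConfig(
        dims=DIMS, n_subjects=60, prevalence=0.5,
        hypo_regions=HYPO, hyper_regions=HYPER,
        effect_size=0.15, noise_sd=0.05, smooth_fwhm_vox=2.0, seed=1,
    )
    return ps.generate_cohort(cfg, toy_atlas)


@pytest.fixture(scope="session")
def normalized_stack(toy_atlas, fdg_cohort):
    norm = ps.ReferenceRegionNormalizer(atlas=toy_atlas).fit(None)
    return norm.transform(fdg_cohort.stack())


@pytest.fixture(scope="session")
def trained_classifier(normalized_stack, fdg_cohort):
    clf = ps.SliceSubmoduleClassifier(
        conv_filters=(4, 8, 16, 16), max_epochs=5, random_state=0,
    )
    clf.fit(normalized_stack, fdg_cohort.labels)
    return clf


@pytest.fixture(scope="session")
def amyloid_cohort(toy_atlas):
    cfg = ps.SyntheticCohortConfig(
        dims=DIMS, n_subjects=40, prevalence=0.4, noise_sd=0.02,
        smooth_fwhm_vox=0.0, seed=7,
    )
    return ps.generate_amyloid_cohort(cfg, toy_atlas, threshold=1.4, margin=0.2)


def auc_all_pairs(y, proba):
    """Independent AUC oracle: concordant positive/negative pairs, ties = 1/2."""
    y = np.asarray(y)
    pos = np.asarray(proba)[y == 1]
    neg = np.asarray(proba)[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def flood_fill_components(binary, connectivity=18):
    """Independent connected-component oracle (BFS)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manh = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manh > 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offsets.append((dx, dy, dz))
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= w[i] < dims[i] for i in range(3)):
                    if binary[w] and not visited[w]:
                        visited[w] = True
                        stack.append(w)
        comps.append(frozenset(comp))
    return comps
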