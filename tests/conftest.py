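"""Shared fixtures: phantoms, a small composite corpus, a study-scale corpus.

Everything is generated programmatically with fixed seeds; the session-scoped
corpora are built once and shared across evaluation and acceptance tests.
"""

from __future__ import annotations

import pytest

from pwml.compositor import build_composites
from pwml.lesion_bank import extract_lesions
from pwml.phantom import (
    LesionSpec,
    PhantomParams,
    generate_backgrounds,
    generate_slice,
    generate_source_case,
    inject_lesions_with_records,
)
from pwml.preprocess import auto_contrast
from pwml.refdetect import detect


@pytest.fixture(scope="session")
def phantom_slice():
    """One default phantom slice + tissue map."""
    return generate_slice(PhantomParams(), seed=1)


@pytest.fixture(scope="session")
def lesioned_phantom():
    """Phantom with 5 injected 5-6 px lesions and their provenance records."""
    img, tis = generate_slice(PhantomParams(), seed=1)
    inj, records = inject_lesions_with_records(
        img, tis, LesionSpec(count=5, contrast=40.0, diameter_px=(5.0, 6.0)), seed=3
    )
    return inj, tis, records


def _build_corpus(case_defs, n_backgrounds, seed):
    lesion_slices = []
    for c, (total, n_slices) in enumerate(case_defs):
        for sl in generate_source_case(f"case{c}", total, n_slices, seed=seed):
            norm = auto_contrast(sl.image)
            norm.image_id = sl.slice_id
            patches = extract_lesions(norm, sl.tissue, source_id=sl.slice_id)
            lesion_slices.append((sl.slice_id, patches))
    backgrounds = [
        (auto_contrast(img), tis)
        for img, tis in generate_backgrounds(n_backgrounds, seed=seed)
    ]
    composites = build_composites(lesion_slices, backgrounds, seed=seed)
    return lesion_slices, backgrounds, composites


@pytest.fixture(scope="session")
def small_corpus():
    """Two small source cases x 6 backgrounds -> 42 composites."""
    return _build_corpus([(9, 4), (8, 3)], n_backgrounds=6, seed=5)


@pytest.fixture(scope="session")
def study_scale_corpus():
    """The study-scale geometry: 13 lesion slices x 72 normals."""
    return _build_corpus([(19, 7), (17, 6)], n_backgrounds=72, seed=11)


@pytest.fixture(scope="session")
def small_corpus_detections(small_corpus):
    """Reference-detector output on every small-corpus composite."""
    _, _, composites = small_corpus
    dets_by, truths_by, tissue_by = {}, {}, {}
    for rec in composites:
        img = rec.image.copy()
        img.image_id = rec.image_id
        dets_by[rec.image_id] = detect(img)
        truths_by[rec.image_id] = rec.boxes
        tissue_by[rec.image_id] = rec.tissue
    return dets_by, truths_by, tissue_by
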