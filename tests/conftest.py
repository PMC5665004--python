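"""Shared fixtures: an in-memory store with staff accounts, and one small
generated collection reused by the image-facing tests."""

from __future__ import annotations

import shutil

import pytest

from colldigi.datastore import Store
from colldigi.synthetic import GenerationConfig, generate_collection


@pytest.fixture()
def store() -> Store:
    """Fresh in-memory store with one user per role."""
    s = Store()
    s.add_user("tr", {"transcriber"})
    s.add_user("dm", {"data_manager"})
    s.add_user("geo", {"georeferencer"})
    s.add_user("scr", {"scrutineer"})
    s.add_user("nobody", set())
    return s


@pytest.fixture(scope="session")
def _small_collection_src(tmp_path_factory):
    """Generated once per session; never handed to tests directly because
    processing renames the files in place."""
    root = tmp_path_factory.mktemp("coll-src")
    cfg = GenerationConfig(
        n_drawers=2, specimens_per_drawer=6, seed=3, double_sided_fraction=0.25
    )
    manifest = generate_collection(cfg, root)
    return root, manifest


@pytest.fixture()
def small_collection(_small_collection_src, tmp_path):
    """A fresh copy of the 12-specimen synthetic tree (clean barcodes, some
    double-sided)."""
    src, manifest = _small_collection_src
    root = tmp_path / "coll"
    shutil.copytree(src, root)
    return root, manifest


def add_plain_specimen(store: Store, barcode, drawer="Drawer01", taxon="Aus bus",
                       site=None, date_verbatim=None, collectors=None):
    """Create a specimen row directly (no image files involved)."""
    tv = store.ensure_variant("taxon", taxon)
    sid = store.create_specimen(barcode, drawer, tv)
    fields = {}
    if site is not None:
        fields["site_variant_id"] = store.ensure_variant("site", site)
    if date_verbatim is not None:
        fields["date_verbatim"] = date_verbatim
    if collectors:
        for c in collectors:
            store.ensure_variant("party", c)
        fields["collectors"] = ";".join(collectors)
    if fields:
        store.update_specimen(sid, **fields)
    return sid
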