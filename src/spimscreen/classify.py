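"""Cell-cycle phase classification of segmented nuclei.

Two classifiers are provided, mirroring the screen's model comparison:

* a random forest on the 13 per-nucleus Haralick texture features;
* a small VGG-style CNN applied to 2D slices of each 3D segment (XY, XZ
  and YZ orientations), whose per-slice phase probabilities are summed and
  the class with the highest summed likelihood is assigned to the nucleus
  (slice voting).

Both record their stratified 90/10 holdout accuracy at training time.  The
4-class phase set is {interphase, prophase, metaphase, anaphase}; a 6-class
variant adds {macronuclei, apoptotic_condensed_DNA} for the 2D pre-screen.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .nn import TinyVGG
from .segmentation import LabelVolume
from .volume import FusedVolume

PHASE_CLASSES_4 = ("interphase", "prophase", "metaphase", "anaphase")
PHASE_CLASSES_6 = PHASE_CLASSES_4 + ("macronuclei", "apoptotic_condensed_DNA")

ORIENTATIONS = ("XY", "XZ", "YZ")


@dataclass
class SliceSet:
    """2D patches of one nucleus, one per plane per orientation."""

    nucleus_id: int
    patches: np.ndarray  # (n, patch, patch) float32 in [0, 1]
    orientations: list  # per patch: "XY" | "XZ" | "YZ"
    slice_indices: list  # per patch: plane index within the crop

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class ClassifierBundle:
    """A trained classifier with its fixed class order and training metadata."""

    kind: str  # "rf" | "cnn"
    model: object
    class_order: tuple
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"kind": self.kind, "class_order": list(self.class_order),
                "metadata": self.metadata}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
        if self.kind == "cnn":
            d, arrays = self.model.state_dict()
            np.savez(path, __meta__=json.dumps(d), **arrays)
        else:
            with open(path, "wb") as fh:
                pickle.dump(self.model, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierBundle":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta["kind"] == "cnn":
            with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
                arrays = {k: z[k] for k in z.files if k != "__meta__"}
                net_meta = json.loads(str(z["__meta__"]))
            model = TinyVGG.from_state(net_meta, arrays)
        else:
            with open(path, "rb") as fh:
                model = pickle.load(fh)
        return cls(meta["kind"], model, tuple(meta["class_order"]), meta["metadata"])


# --------------------------------------------------------------------------
# slice extraction
# --------------------------------------------------------------------------


def extract_slices(
    volume: FusedVolume,
    labels: LabelVolume,
    nucleus_id: int,
    patch_size: int = 32,
    n_slices: int | None = None,
    masked: bool = True,
) -> SliceSet:
    """Cut per-orientation 2D patches out of one segmented nucleus.

    The segment's bounding box is expanded to a cube (so patch aspect is
    preserved across orientations); each plane of the cube intersecting the
    segment yields one patch per orientation, masked to the segment
    (optional), min–max normalized to [0, 1] and resized to
    ``patch_size``².  ``n_slices`` restricts extraction to that many central
    planes per orientation.
    """
    lab = labels.labels
    bbox = labels.bounding_box(nucleus_id)
    if bbox is None:
        raise ValueError(f"nucleus {nucleus_id} is empty")
    where = np.argwhere(lab[bbox] == nucleus_id) + [s.start for s in bbox]
    if len(where) == 0:
        raise ValueError(f"nucleus {nucleus_id} is empty")
    lo = where.min(axis=0)
    hi = where.max(axis=0) + 1
    side = int((hi - lo).max())
    center = (lo + hi) / 2.0
    lo_c = np.maximum(np.floor(center - side / 2).astype(int), 0)
    hi_c = np.minimum(lo_c + side, lab.shape)
    lo_c = np.maximum(hi_c - side, 0)
    sl = tuple(slice(a, b) for a, b in zip(lo_c, hi_c))
    img = np.asarray(volume.data, dtype=float)[sl]
    m = lab[sl] == nucleus_id
    if masked:
        img = np.where(m, img, 0.0)

    patches, orients, indices = [], [], []
    for orient, axis in zip(ORIENTATIONS, (0, 1, 2)):  # planes along z, y, x
        present = np.unique(where[:, axis]) - lo_c[axis]
        present = present[(present >= 0) & (present < img.shape[axis])]
        if n_slices is not None and len(present) > n_slices:
            mid = np.searchsorted(present, np.median(where[:, axis]) - lo_c[axis])
            half = n_slices // 2
            start = int(np.clip(mid - half, 0, len(present) - n_slices))
            present = present[start:start + n_slices]
        for k in present:
            plane = np.take(img, int(k), axis=axis)
            lo_v, hi_v = plane.min(), plane.max()
            if hi_v > lo_v:
                plane = (plane - lo_v) / (hi_v - lo_v)
            else:
                plane = np.zeros_like(plane)
            if plane.shape != (patch_size, patch_size):
                plane = resize(plane, (patch_size, patch_size), order=1,
                               anti_aliasing=False, preserve_range=True)
            patches.append(plane.astype(np.float32))
            orients.append(orient)
            indices.append(int(k))
    return SliceSet(nucleus_id, np.stack(patches), orients, indices)


# --------------------------------------------------------------------------
# random forest on Haralick features
# --------------------------------------------------------------------------


def train_rf(
    features: np.ndarray,
    labels,
    seed: int = 0,
    class_order=None,
    n_estimators: int = 200,
    holdout_fraction: float = 0.1,
) -> ClassifierBundle:
    """Train the Haralick random forest with a stratified 90/10 holdout."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    ok = np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    classes = tuple(class_order) if class_order is not None else tuple(sorted(set(y)))
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    yi = np.array([classes.index(c) for c in y])
    Xtr, Xte, ytr, yte = train_test_split(
        X, yi, test_size=holdout_fraction, stratify=yi, random_state=seed
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        class_weight="balanced", random_state=seed, n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    acc = float((rf.predict(Xte) == yte).mean())
    meta = {"n_per_class": {c: int((y == c).sum()) for c in classes},
            "seed": seed, "holdout_accuracy": acc}
    return ClassifierBundle("rf", rf, classes, meta)


def classify_rf(bundle: ClassifierBundle, features: np.ndarray) -> np.ndarray:
    """Class probabilities (n, n_classes) in the bundle's class order."""
    X = np.asarray(features, dtype=float)
    proba = np.zeros((len(X), len(bundle.class_order)))
    ok = np.isfinite(X).all(axis=1)
    if ok.any():
        p = bundle.model.predict_proba(X[ok])
        for col, ci in enumerate(bundle.model.classes_):
            proba[ok, ci] = p[:, col]
    proba[~ok] = 1.0 / len(bundle.class_order)
    return proba


# --------------------------------------------------------------------------
# CNN on slices
# --------------------------------------------------------------------------


def train_cnn(
    patches: np.ndarray,
    labels,
    seed: int = 0,
    class_order=None,
    groups=None,
    epochs: int = 8,
    channels=(16, 32, 64),
    hidden: int = 128,
    holdout_fraction: float = 0.1,
    lr: float = 1e-3,
) -> ClassifierBundle:
    """Train the slice CNN with a stratified 90/10 holdout.

    ``groups`` (e.g. nucleus ids) keeps all slices of one nucleus on the
    same side of the split, so the holdout accuracy is not inflated by
    near-duplicate slices.
    """
    X = np.asarray(patches, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("patches must be a (n, size, size) array of equal-size patches")
    y = np.asarray(labels)
    classes = tuple(class_order) if class_order is not None else tuple(sorted(set(y)))
    if any((y == c).sum() == 0 for c in classes):
        raise ValueError("every class must be represented")
    yi = np.array([classes.index(c) for c in y])

    if groups is not None:
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        gy = yi[first]
        strat = gy if np.bincount(gy).min() >= 2 else None
        gtr, gte = train_test_split(uniq, test_size=holdout_fraction,
                                    stratify=strat, random_state=seed)
        tr = np.isin(groups, gtr)
        te = ~tr
    else:
        idx = np.arange(len(X))
        tr_idx, te_idx = train_test_split(idx, test_size=holdout_fraction,
                                          stratify=yi, random_state=seed)
        tr = np.zeros(len(X), bool)
        tr[tr_idx] = True
        te = ~tr

    net = TinyVGG(input_size=X.shape[1], n_classes=len(classes),
                  channels=channels, hidden=hidden, seed=seed)
    net.fit(X[tr], yi[tr], epochs=epochs, seed=seed, lr=lr)
    pred = net.predict_proba(X[te]).argmax(axis=1)
    acc = float((pred == yi[te]).mean())
    meta = {"n_per_class": {str(c): int((y == c).sum()) for c in classes},
            "seed": seed, "holdout_accuracy": acc, "epochs": epochs}
    return ClassifierBundle("cnn", net, classes, meta)


def predict_slices(bundle: ClassifierBundle, patches: np.ndarray) -> np.ndarray:
    """Per-slice class probabilities in the bundle's class order."""
    return bundle.model.predict_proba(np.asarray(patches, dtype=np.float32))


# --------------------------------------------------------------------------
# summed-likelihood voting
# --------------------------------------------------------------------------


def classify_segment(per_slice_probabilities: np.ndarray, class_order=PHASE_CLASSES_4):
    """Aggregate per-slice probabilities into one phase call.

    The class with the highest *sum* of per-slice probabilities wins; the
    aggregated probabilities are the normalized sums.  Exact ties resolve
    to the earliest class in ``class_order``.
    """
    p = np.asarray(per_slice_probabilities, dtype=float)
    if p.ndim != 2 or len(p) == 0:
        raise ValueError("need at least one slice of probabilities")
    sums = p.sum(axis=0)
    agg = sums / sums.sum()
    return class_order[int(np.argmax(sums))], agg
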