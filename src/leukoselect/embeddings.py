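"""Optional deep-embedding adapter.

The descriptor bank is the default feature source; this module defines the
contract for swapping in a pretrained CNN backbone (penultimate-layer,
globally pooled activations, one row per sample). Pretrained weights require
a download, so the adapter raises :class:`BackboneUnavailableError` unless a
local torch/torchvision install with cached weights exists — downstream
selectors are agnostic to which source produced the rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import BackboneUnavailableError
from .features import FeatureMatrix
from .synthetic import DatasetManifest, load_samples

__all__ = ["deep_embed", "KNOWN_BACKBONES"]

#: published penultimate-layer embedding widths
KNOWN_BACKBONES = {
    "googlenet": 1024,
    "resnet50": 2048,
    "alexnet": 4096,
    "squeezenet": 512,
}


def deep_embed(manifest: DatasetManifest, backbone: str, root: str | Path = ".") -> FeatureMatrix:
    """Embed every manifest image with a pretrained backbone.

    Output contract: one row per sample in manifest order, column count equal
    to the backbone's embedding width, deterministic in inference mode. The
    returned object is interchangeable with the descriptor bank's output.
    """
    if backbone not in KNOWN_BACKBONES:
        raise ValueError(f"unknown backbone {backbone!r}; known: {sorted(KNOWN_BACKBONES)}")
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise BackboneUnavailableError(
            f"backbone {backbone!r} needs torch/torchvision with locally cached pretrained "
            "weights; none found. Use the descriptor bank (leukoselect.features) instead."
        ) from exc
    return _embed_with_torch(manifest, backbone, root)


def _embed_with_torch(manifest: DatasetManifest, backbone: str, root: str | Path) -> FeatureMatrix:
    import torch
    import torchvision.models as models
    import torchvision.transforms.functional as TF

    builders = {
        "googlenet": lambda: models.googlenet(weights="DEFAULT"),
        "resnet50": lambda: models.resnet50(weights="DEFAULT"),
        "alexnet": lambda: models.alexnet(weights="DEFAULT"),
        "squeezenet": lambda: models.squeezenet1_1(weights="DEFAULT"),
    }
    try:
        net = builders[backbone]()
    except Exception as exc:  # weights not cached locally
        raise BackboneUnavailableError(
            f"pretrained weights for {backbone!r} are not available locally: {exc}"
        ) from exc
    net.eval()
    trunk = torch.nn.Sequential(*list(net.children())[:-1])
    rows = []
    samples = load_samples(manifest, root)
    with torch.no_grad():
        for sample in samples:
            x = torch.from_numpy(np.ascontiguousarray(sample.pixels.transpose(2, 0, 1))).float()
            x = TF.resize(x.unsqueeze(0), [224, 224], antialias=True)
            emb = trunk(x).flatten(1).squeeze(0).numpy()
            rows.append(emb)
    values = np.vstack(rows)
    names = [f"{backbone}_emb_{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values, names, manifest.labels, [r.sample_id for r in manifest.records])
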