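"""Packaged loop-connection ABEGO menus.

Rather than sampling every torsion-bin string of a given length, loop
segments draw from short menus of connector conformations commonly
observed between secondary-structure elements — separate menus for
helix-to-strand, strand-to-helix, strand-to-strand (hairpin) and
helix-to-helix connections.  The menus live in ``data/loop_menus.yaml`` so
users can extend them; a fold definition may also override the menu per
loop segment.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

_CONNECTION_KEYS = {
    ("helix", "strand"): "alpha_beta",
    ("strand", "helix"): "beta_alpha",
    ("strand", "strand"): "beta_beta",
    ("helix", "helix"): "alpha_alpha",
}


@lru_cache(maxsize=1)
def load_loop_menus(path=None) -> dict[str, list[str]]:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    text = resources.files("foldsmith.data").joinpath("loop_menus.yaml").read_text()
    return yaml.safe_load(text)


def loop_menu_for(fold, loop_name: str) -> list[str]:
    """Connector menu for a loop, keyed by its flanking element kinds.

    Terminal loops (no flanking element on one side) fall back to the
    generic menu.
    """
    menus = load_loop_menus()
    segs = fold.segments
    idx = next(i for i, s in enumerate(segs) if s.name == loop_name)
    before = segs[idx - 1].kind if idx > 0 else None
    after = segs[idx + 1].kind if idx + 1 < len(segs) else None
    key = _CONNECTION_KEYS.get((before, after))
    if key is None:
        return list(menus.get("generic", []))
    return list(menus[key])
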