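"""Chromosome-name normalization.

Germplasm genotype files and resequencing pipelines disagree on naming:
the soybean reference uses ``Gm01``-style identifiers while callers emit
``chr1``, ``Chr01`` or bare ``1``. All ingestion paths funnel names
through :func:`normalize_chrom` so that ``Gm01``, ``chr1``, ``01`` and
``1`` all key the same site. A caller-supplied alias table wins over the
built-in rules, which lets non-numeric scaffolds be mapped explicitly.
"""

from __future__ import annotations

import re

_PREFIX = re.compile(r"^(chr|gm)0*", re.IGNORECASE)
_LEADING_ZEROS = re.compile(r"^0+(?=\d)")


def normalize_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Return the canonical form of a chromosome identifier.

    Rules, applied in order:

    1. exact match in ``aliases`` (case-sensitive) returns the mapped value;
    2. a leading ``chr``/``Chr``/``Gm``/``gm`` prefix is stripped together
       with any zero-padding (``Gm01`` -> ``1``, ``chr07`` -> ``7``);
    3. a purely numeric name has leading zeros removed (``01`` -> ``1``);
    4. anything else is returned unchanged (scaffolds keep their names).
    """
    name = name.strip()
    if aliases and name in aliases:
        return aliases[name]
    stripped = _PREFIX.sub("", name)
    if stripped and stripped != name:
        # only accept the prefix-strip when a sensible token remains
        if stripped[0].isdigit():
            return _LEADING_ZEROS.sub("", stripped)
        return name
    if name.isdigit():
        return str(int(name))
    return name
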