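"""Wildcard discovery of study input files.

A path template with named wildcards, e.g. ``sub-{sub}/run-{run}.fif``,
is matched against the filesystem; every existing path yields one session
whose id joins the wildcard values with ``-`` (so ``sub-008/run-03.fif``
under the template above becomes session ``008-03``).  A subset of
wildcards can be fixed to select, e.g., one subject.
"""

from __future__ import annotations

import re
from pathlib import Path

__all__ = ["find_sessions"]

_WILDCARD = re.compile(r"\{(\w+)\}")


def find_sessions(pattern: str | Path, **fixed) -> list[tuple[str, Path]]:
    """Return deterministically sorted (session_id, path) pairs matching a
    template with named wildcards.

    Parameters
    ----------
    pattern : str or Path
        Path template containing at least one ``{name}`` wildcard.
    **fixed
        Wildcard values to pin, e.g. ``sub="001"`` — only sessions whose
        wildcard takes exactly that value are returned.
    """
    pattern = str(pattern)
    names = _WILDCARD.findall(pattern)
    if not names:
        raise ValueError("pattern must contain at least one {name} wildcard")
    unknown = set(fixed) - set(names)
    if unknown:
        raise ValueError(f"fixed wildcards not in pattern: {sorted(unknown)}")

    glob_pat = ""
    regex_pat = ""
    pos = 0
    for m in _WILDCARD.finditer(pattern):
        literal = pattern[pos : m.start()]
        glob_pat += literal
        regex_pat += re.escape(literal)
        name = m.group(1)
        if name in fixed:
            val = str(fixed[name])
            glob_pat += val
            regex_pat += f"(?P<{name}>{re.escape(val)})"
        else:
            glob_pat += "*"
            regex_pat += f"(?P<{name}>[^/]+)"
        pos = m.end()
    literal = pattern[pos:]
    glob_pat += literal
    regex_pat += re.escape(literal) + r"\Z"

    glob_path = Path(glob_pat)
    if glob_path.is_absolute():
        root = Path(glob_path.root)
        rel = glob_path.relative_to(root)
    else:
        root, rel = Path("."), glob_path
    rx = re.compile(regex_pat)
    out = []
    for p in root.glob(str(rel)):
        m = rx.search(str(p))
        if m is None:
            continue
        values = [m.group(n) for n in dict.fromkeys(names)]
        out.append(("-".join(values), p))
    out.sort(key=lambda sp: str(sp[1]))
    return out
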