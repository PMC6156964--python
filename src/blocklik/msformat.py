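"""Conversion between demographic models and ms-style command-line strings.

The structured model (``DemographicModel``) is canonical; this converter
exists for interoperability with the large ecosystem of ms-flavoured tools.
Both directions use the same scaling as ms: times in ``4*N_0`` generations,
sizes as ratios to ``N_0``, growth rates per ``4*N_0`` generations, migration
entries ``M_ij = 4*N_0*m_ij`` where ``m_ij`` is the fraction of subpopulation
``i`` made up of migrants from ``j`` each generation.

Supported flags: ``-I -n -g -m -ej -en -eg -em -es`` (an ``-es t i p``
population split must be immediately followed by ``-ej t <new> j`` — the
standard idiom for an admixture pulse, which is what it is parsed back
into).  ``-t``/``-r`` are data-scale flags, not demography, and are ignored.
"""

from __future__ import annotations

import shlex

from .demography import DemographicEvent, DemographicModel, PopulationSpec

__all__ = ["to_ms_args", "parse_ms_args"]


def to_ms_args(model: DemographicModel) -> str:
    """Render the demography as an ms-style argument string (no -t/-r)."""
    model.validate()
    nref = model.reference_size
    idx = {p.name: i + 1 for i, p in enumerate(model.populations)}
    npop = len(model.populations)
    parts: list[str] = []
    if npop > 1:
        parts += ["-I", str(npop)] + ["0"] * npop  # sample sizes live elsewhere
    for p in model.populations:
        if p.initial_size != nref:
            parts += ["-n", str(idx[p.name]), _fmt(p.initial_size / nref)]
        if p.growth_rate != 0.0:
            parts += ["-g", str(idx[p.name]), _fmt(p.growth_rate * 4.0 * nref)]
    for e in model.events:
        t = _fmt(e.time)
        if e.kind == "migration_change":
            donor, recipient = e.participants
            flag = ["-m"] if e.time == 0 else ["-em", t]
            parts += flag + [str(idx[recipient]), str(idx[donor]), _fmt(e.value)]
        elif e.kind == "split_join":
            derived, ancestral = e.participants
            parts += ["-ej", t, str(idx[derived]), str(idx[ancestral])]
        elif e.kind == "size_change":
            parts += ["-en", t, str(idx[e.participants[0]]), _fmt(e.value / nref)]
        elif e.kind == "growth_change":
            parts += ["-eg", t, str(idx[e.participants[0]]), _fmt(e.value * 4.0 * nref)]
        elif e.kind == "admixture_pulse":
            donor, recipient = e.participants
            # -es splits the recipient; the emitted fraction joins the donor
            parts += ["-es", t, str(idx[recipient]), _fmt(1.0 - e.value)]
            parts += ["-ej", t, str(npop + 1), str(idx[donor])]
    return " ".join(parts)


def _fmt(x: float) -> str:
    return format(x, ".17g")


def parse_ms_args(
    args: str | list[str],
    reference_size: float,
    mutation_rate: float,
    recombination_rate: float = 0.0,
) -> DemographicModel:
    """Parse an ms-style demography string into a model.

    ms carries no absolute scale, so ``reference_size`` (N_0, individuals)
    and the per-site rates must be given.  Population names are ``pop1`` ...
    ``popX`` in flag order.
    """
    tokens = shlex.split(args) if isinstance(args, str) else list(args)
    nref = reference_size
    npop = 1
    sizes: dict[int, float] = {}
    growth: dict[int, float] = {}
    events: list[DemographicEvent] = []
    i = 0

    def name(j: int) -> str:
        if not 1 <= j <= npop:
            raise ValueError(f"population index {j} out of range (npop={npop})")
        return f"pop{j}"

    def take(n: int) -> list[str]:
        nonlocal i
        if i + n > len(tokens):
            raise ValueError(f"flag {tokens[i - 1]!r}: expected {n} arguments")
        out = tokens[i : i + n]
        i += n
        return out

    while i < len(tokens):
        flag = tokens[i]
        i += 1
        if flag == "-I":
            (n_str,) = take(1)
            npop = int(n_str)
            take(npop)  # per-deme sample sizes: layout concern, ignored
            # optional symmetric migration rate
            if i < len(tokens) and not tokens[i].startswith("-"):
                (m_str,) = take(1)
                m = float(m_str) / (npop - 1)
                for a in range(1, npop + 1):
                    for b in range(1, npop + 1):
                        if a != b and m > 0:
                            events.append(
                                DemographicEvent(
                                    "migration_change", 0.0, (name(b), name(a)), m
                                )
                            )
        elif flag == "-n":
            j, x = take(2)
            sizes[int(j)] = float(x) * nref
        elif flag == "-g":
            j, a = take(2)
            growth[int(j)] = float(a) / (4.0 * nref)
        elif flag == "-m":
            j, k, m = take(3)
            events.append(
                DemographicEvent(
                    "migration_change", 0.0, (name(int(k)), name(int(j))), float(m)
                )
            )
        elif flag == "-em":
            t, j, k, m = take(4)
            events.append(
                DemographicEvent(
                    "migration_change",
                    float(t),
                    (name(int(k)), name(int(j))),
                    float(m),
                )
            )
        elif flag == "-ej":
            t, j, k = take(3)
            events.append(
                DemographicEvent(
                    "split_join", float(t), (name(int(j)), name(int(k)))
                )
            )
        elif flag == "-en":
            t, j, x = take(3)
            events.append(
                DemographicEvent(
                    "size_change", float(t), (name(int(j)),), float(x) * nref
                )
            )
        elif flag == "-eg":
            t, j, a = take(3)
            events.append(
                DemographicEvent(
                    "growth_change", float(t), (name(int(j)),), float(a) / (4.0 * nref)
                )
            )
        elif flag == "-es":
            t, j, p = take(3)
            # must be followed by -ej t (npop+1) k: the admixture-pulse idiom
            if i + 4 > len(tokens) or tokens[i] != "-ej":
                raise ValueError("-es must be followed by -ej of the new deme")
            _, t2, new, k = tokens[i : i + 4]
            i += 4
            if float(t2) != float(t) or int(new) != npop + 1:
                raise ValueError(
                    "-es/-ej pair must share a time and join the new deme"
                )
            events.append(
                DemographicEvent(
                    "admixture_pulse",
                    float(t),
                    (name(int(k)), name(int(j))),
                    1.0 - float(p),
                )
            )
        elif flag in ("-t", "-r"):
            take(1 if flag == "-t" else 2)
        else:
            raise ValueError(f"unsupported ms flag {flag!r}")
    pops = [
        PopulationSpec(
            f"pop{j}",
            initial_size=sizes.get(j, nref),
            growth_rate=growth.get(j, 0.0),
        )
        for j in range(1, npop + 1)
    ]
    events.sort(key=lambda e: e.time)
    model = DemographicModel(
        populations=pops,
        events=events,
        reference_size=nref,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
    )
    # island-type strings (no join chain) parse fine; simulation-side
    # validation stays strict about a single root
    model.validate(require_single_root=False)
    return model
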