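"""Shared fixtures: small hand-built trees and synthetic datasets."""

from __future__ import annotations

import pytest

from httscan import HostTree


@pytest.fixture(scope="session")
def fig_tree() -> HostTree:
    """Six-tip chronogram with two reference genomes (SPX, SPY).

    Topology (SP4,(((SP1,SP2),SPX),(SP3,SPY))): the only node separating
    the two reference genomes is N1, whose age (75 My) equals the
    divergence of SP2 and SP3 but is younger than that of SP2 and SP4.
    """
    children = {
        "R": ("SP4", "N1"),
        "N1": ("N2", "N4"),
        "N2": ("N3", "SPX"),
        "N3": ("SP1", "SP2"),
        "N4": ("SP3", "SPY"),
    }
    ages = {"R": 100.0, "N1": 75.0, "N2": 50.0, "N3": 25.0, "N4": 50.0,
            "SP1": 0.0, "SP2": 0.0, "SP3": 0.0, "SP4": 0.0, "SPX": 0.0,
            "SPY": 0.0}
    orders = {t: "ORD01" for t in ("SP1", "SP2", "SPX")}
    orders.update({t: "ORD02" for t in ("SP3", "SP4", "SPY")})
    return HostTree(children, ages, orders=orders, references={"SPX", "SPY"})


@pytest.fixture(scope="session")
def balanced_tree() -> HostTree:
    """((A,B),(C,D)) with node ages 10/20/40 My."""
    children = {"R": ("NAB", "NCD"), "NAB": ("A", "B"), "NCD": ("C", "D")}
    ages = {"R": 40.0, "NAB": 10.0, "NCD": 20.0,
            "A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0}
    orders = {"A": "ORD01", "B": "ORD01", "C": "ORD02", "D": "ORD02"}
    return HostTree(children, ages, orders=orders, references={"A", "C"})
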