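"""Registered-domain extraction and the domain-quality lookup table.

URL domains are reduced to their registered domain (public-suffix rule):
``www.example.com/this-is-an-example.html`` → ``example.com``.  Subdomains are
stripped and the public suffix kept, including common multi-label suffixes
such as ``co.uk`` or ``com.au``.
"""

from __future__ import annotations

import logging
from urllib.parse import urlparse

import pandas as pd

__all__ = ["registered_domain", "DomainQualityTable"]

logger = logging.getLogger(__name__)

# Compact public-suffix rule set: a registered domain is the last two labels,
# or the last three when the final two labels form one of these suffixes.
_MULTI_LABEL_SUFFIXES = {
    "co.uk", "org.uk", "ac.uk", "gov.uk", "me.uk", "net.uk",
    "com.au", "net.au", "org.au", "edu.au", "gov.au",
    "co.jp", "ne.jp", "or.jp", "ac.jp", "go.jp",
    "co.in", "net.in", "org.in", "gen.in", "firm.in",
    "com.br", "net.br", "org.br", "gov.br",
    "co.nz", "net.nz", "org.nz", "govt.nz",
    "co.za", "org.za", "gov.za",
    "com.mx", "org.mx", "gob.mx",
    "com.cn", "net.cn", "org.cn", "gov.cn",
    "com.sg", "com.hk", "com.tw", "com.ar", "com.tr", "com.ua",
    "co.kr", "or.kr", "go.kr",
}


def registered_domain(url: str) -> str | None:
    """Extract the registered domain of a URL; ``None`` if unparseable.

    Accepts scheme-less inputs ("www.example.com/page") as a convenience.
    """
    if not url or not isinstance(url, str):
        return None
    raw = url.strip().lower()
    if "://" not in raw:
        raw = "http://" + raw
    try:
        host = urlparse(raw).hostname
    except ValueError:
        return None
    if not host:
        return None
    labels = host.strip(".").split(".")
    if len(labels) < 2 or any(not lb for lb in labels):
        return None
    if len(labels) >= 3 and ".".join(labels[-2:]) in _MULTI_LABEL_SUFFIXES:
        return ".".join(labels[-3:])
    return ".".join(labels[-2:])


class DomainQualityTable:
    """Mapping registered domain → quality rating in [0, 1].

    Keys are lower-cased registered domains; lookups normalise the query URL
    or hostname through :func:`registered_domain` first.
    """

    def __init__(self, ratings: dict[str, float]):
        clean: dict[str, float] = {}
        for dom, q in ratings.items():
            key = registered_domain(dom) or dom.strip().lower()
            q = float(q)
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"quality rating for {dom!r} outside [0, 1]: {q}")
            clean[key] = q
        self._ratings = clean

    @classmethod
    def from_csv(cls, path) -> "DomainQualityTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["domain"], df["quality"])))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DomainQualityTable":
        return cls(dict(zip(df["domain"], df["quality"])))

    def __len__(self) -> int:
        return len(self._ratings)

    def __contains__(self, domain: str) -> bool:
        return domain in self._ratings

    def rating_for_domain(self, domain: str) -> float | None:
        return self._ratings.get(domain)

    def rating_for_url(self, url: str) -> float | None:
        dom = registered_domain(url)
        if dom is None:
            logger.warning("skipping malformed URL: %r", url)
            return None
        return self._ratings.get(dom)

    def tweet_score(self, urls: list[str]) -> float | None:
        """Min-rule tweet score: the lowest rating among the tweet's rated URLs.

        Returns ``None`` when no URL resolves to a rated domain, in which case
        the tweet is excluded from that day's quality denominator.
        """
        ratings = [r for r in (self.rating_for_url(u) for u in urls) if r is not None]
        return min(ratings) if ratings else None
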