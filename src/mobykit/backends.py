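"""Access-layer backends and stackable layers.

Every module of the framework is split in two layers: an *Access* layer that
maps a concrete metadata source into the common record model (the backends
below) and an *Interface* layer (:class:`mobykit.registry.Registry`) that
exposes the uniform public API.  The two communicate through the small
contract defined by :class:`Backend`; extra layers such as the cache follow
the same contract and can be stacked without changing the Interface.

Two in-memory accesses are provided: a native-edit one, and one that models
repositories without an edit API (edits are emulated by the Interface layer
as deregister + register in a single transaction).
"""

from __future__ import annotations

import dataclasses
from typing import Any, Iterable

from .errors import DuplicateName, NotFound, UnknownField


class Backend:
    """Contract every access/layer implements.

    ``list``/``get`` never mutate.  ``add`` of a duplicate id is an error.
    ``update`` is optional: accesses whose source repository cannot edit in
    place advertise ``native_edit = False`` and the Interface layer emulates
    the edit via ``deregister`` + ``register``.
    """

    native_edit: bool = True

    def list(self) -> list[Any]:
        raise NotImplementedError

    def get(self, resource_id: str) -> Any:
        raise NotImplementedError

    def add(self, record: Any) -> Any:
        raise NotImplementedError

    def delete(self, resource_id: str) -> None:
        raise NotImplementedError

    def update(self, resource_id: str, changes: dict) -> Any:
        raise NotImplementedError

    def register(self, record: Any) -> Any:
        """Insert a record preserving its existing id (re-registration)."""
        raise NotImplementedError

    def deregister(self, resource_id: str) -> None:
        raise NotImplementedError


class MemoryBackend(Backend):
    """In-memory access with native editing."""

    native_edit = True

    def __init__(self) -> None:
        self._records: dict[str, Any] = {}

    def list(self) -> list[Any]:
        return [self._records[k] for k in sorted(self._records)]

    def get(self, resource_id: str) -> Any:
        try:
            return self._records[resource_id]
        except KeyError:
            raise NotFound(f"no resource with id {resource_id!r}") from None

    def add(self, record: Any) -> Any:
        if record.id in self._records:
            raise DuplicateName(f"id {record.id!r} already registered")
        self._records[record.id] = record
        return record

    def delete(self, resource_id: str) -> None:
        if resource_id not in self._records:
            raise NotFound(f"no resource with id {resource_id!r}")
        del self._records[resource_id]

    def update(self, resource_id: str, changes: dict) -> Any:
        record = self.get(resource_id)
        names = {f.name for f in dataclasses.fields(record)}
        for key, value in changes.items():
            if key not in names:
                raise UnknownField(f"{type(record).__name__} has no field {key!r}")
            setattr(record, key, value)
        return record

    register = add

    def deregister(self, resource_id: str) -> None:
        self.delete(resource_id)


class ReRegistrationBackend(MemoryBackend):
    """Access over a repository whose API cannot edit records in place.

    Mirrors registries (BioMOBY-style) where the only write primitives are
    register/deregister; the Interface layer emulates updates on top of it.
    """

    native_edit = False

    def update(self, resource_id: str, changes: dict) -> Any:
        raise NotImplementedError("backend does not support native editing")


class CacheLayer(Backend):
    """Stackable read cache.

    Reads are served from the cache when possible; every write passes through
    to the wrapped layer and invalidates the cache, so a cached module is
    observationally identical to an uncached one.
    """

    def __init__(self, inner: Backend) -> None:
        self.inner = inner
        self._by_id: dict[str, Any] = {}
        self._listing: list[Any] | None = None

    @property
    def native_edit(self) -> bool:  # type: ignore[override]
        return self.inner.native_edit

    def _invalidate(self) -> None:
        self._by_id.clear()
        self._listing = None

    def list(self) -> list[Any]:
        if self._listing is None:
            self._listing = self.inner.list()
            for record in self._listing:
                self._by_id[record.id] = record
        return list(self._listing)

    def get(self, resource_id: str) -> Any:
        if resource_id not in self._by_id:
            self._by_id[resource_id] = self.inner.get(resource_id)
        return self._by_id[resource_id]

    def add(self, record: Any) -> Any:
        out = self.inner.add(record)
        self._invalidate()
        return out

    def delete(self, resource_id: str) -> None:
        self.inner.delete(resource_id)
        self._invalidate()

    def update(self, resource_id: str, changes: dict) -> Any:
        out = self.inner.update(resource_id, changes)
        self._invalidate()
        return out

    def register(self, record: Any) -> Any:
        out = self.inner.register(record)
        self._invalidate()
        return out

    def deregister(self, resource_id: str) -> None:
        self.inner.deregister(resource_id)
        self._invalidate()


#: Layers attachable by name through the module configuration.
LAYERS: dict[str, type[Backend]] = {"cache": CacheLayer}

#: Backends selectable by name through the module configuration.
BACKENDS: dict[str, type[Backend]] = {
    "memory": MemoryBackend,
    "reregister": ReRegistrationBackend,
}
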