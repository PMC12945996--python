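"""Bundled lookup tables.

The drug dictionary covers the three marketed TPO-receptor agonists with
their brand names.  The event mapping is a *synthetic stand-in* for the
licensed MedDRA SMQ dictionary: 45 thromboembolic preferred terms assigned
to venous / arterial / mixed narrow categories by package curation.  Users
with a MedDRA licence should load their own mapping instead.
"""

from importlib import resources as _res

from .ingest import DrugDictionary, SmqMap

__all__ = ["default_drug_dictionary", "default_smq_map"]


def _data_path(name: str):
    return _res.files("tpopv").joinpath("data", name)


def default_drug_dictionary() -> DrugDictionary:
    with _res.as_file(_data_path("drug_dictionary.csv")) as p:
        return DrugDictionary.from_csv(p)


def default_smq_map() -> SmqMap:
    with _res.as_file(_data_path("smq_map.synthetic.csv")) as p:
        return SmqMap.from_csv(p)
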