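"""RSML (Root System Markup Language) read/write and mask export.

RSML is the community XML standard for storing root system architectures:
a scene contains plants, plants contain first-order root elements, and
lateral roots are nested inside their parent root element.  Every root
carries a polyline geometry; this writer additionally stores the smoothed
spline as an annotation so that strict readers still parse the polyline.

Only architectures of depth two (first-order roots plus laterals) are
modelled; deeper nesting is rejected on read.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .core import (Plant, Root, RootSystem, point_to_polyline_distance,
                   project_to_polyline)
from .spline import DEFAULT_SPACING, DEFAULT_TENSION, fit_spline
from .targets import ClassMaps

__all__ = ["write_rsml", "read_rsml", "write_masks"]

SOFTWARE_NAME = "rhizotrace"
SOFTWARE_VERSION = "0.1.0"


def _polyline_element(points: np.ndarray) -> etree._Element:
    poly = etree.Element("polyline")
    for x, y in np.asarray(points, dtype=float):
        etree.SubElement(poly, "point", x=f"{x:.6f}", y=f"{y:.6f}")
    return poly


def _root_element(root: Root, rid: str, spline_spacing: float) -> etree._Element:
    el = etree.Element("root", ID=rid, label=f"order-{root.order}")
    geom = etree.SubElement(el, "geometry")
    geom.append(_polyline_element(root.points))
    # smoothed representation kept as an annotation for compatibility
    try:
        spline = root.spline
        if spline is None:
            spline = fit_spline(
                np.asarray(root.points, float), spacing=spline_spacing
            ).sample(8)
        ann_parent = etree.SubElement(el, "annotations")
        ann = etree.SubElement(ann_parent, "annotation", name="spline")
        for x, y in np.asarray(spline, float):
            etree.SubElement(ann, "point", x=f"{x:.6f}", y=f"{y:.6f}")
    except ValueError:
        pass
    return el


def write_rsml(
    rs: RootSystem,
    image_metadata: dict | None = None,
    path: str | Path | None = None,
    spline_spacing: float = DEFAULT_SPACING,
) -> etree._ElementTree:
    """Serialize a root system to an RSML document.

    ``image_metadata`` may carry ``label``, ``size`` (width, height) and
    ``resolution`` entries for the metadata block.  Coordinates are written
    in native-image pixel units, origin top-left.  When ``path`` is given
    the document is also written to disk.
    """
    meta = dict(image_metadata or {})
    rsml = etree.Element("rsml")
    md = etree.SubElement(rsml, "metadata")
    etree.SubElement(md, "version").text = "1"
    etree.SubElement(md, "unit").text = "pixel"
    etree.SubElement(md, "resolution").text = str(meta.get("resolution", 1))
    etree.SubElement(md, "last-modified").text = (
        datetime.date.today().isoformat()
    )
    etree.SubElement(md, "software").text = f"{SOFTWARE_NAME} {SOFTWARE_VERSION}"
    img_el = etree.SubElement(md, "image")
    etree.SubElement(img_el, "label").text = str(meta.get("label", ""))
    if "size" in meta:
        w, h = meta["size"]
        img_el.set("width", str(int(w)))
        img_el.set("height", str(int(h)))

    scene = etree.SubElement(rsml, "scene")
    for pi, plant in enumerate(rs.plants, start=1):
        pl = etree.SubElement(scene, "plant", ID=str(pi), label=f"plant-{pi}")
        props = etree.SubElement(pl, "properties")
        sx, sy = np.asarray(plant.seed, dtype=float)
        etree.SubElement(props, "seed", x=f"{sx:.6f}", y=f"{sy:.6f}")
        order1 = plant.roots_of_order(1)
        laterals = plant.roots_of_order(2)
        for ri, root in enumerate(order1, start=1):
            rel = _root_element(root, f"{pi}.{ri}", spline_spacing)
            children = [lat for lat in laterals if lat.parent is root]
            for li, lat in enumerate(children, start=1):
                rel.append(_root_element(lat, f"{pi}.{ri}.{li}", spline_spacing))
            pl.append(rel)

    tree = etree.ElementTree(rsml)
    if path is not None:
        tree.write(
            str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    return tree


class RSMLError(ValueError):
    """Malformed or unsupported RSML content; message carries the element path."""


def _parse_polyline(geom: etree._Element, where: str) -> np.ndarray:
    poly = geom.find("polyline")
    if poly is None:
        raise RSMLError(f"{where}: geometry without polyline")
    pts = []
    for p in poly.findall("point"):
        try:
            pts.append((float(p.get("x")), float(p.get("y"))))
        except (TypeError, ValueError) as exc:
            raise RSMLError(f"{where}/polyline: bad point attributes") from exc
    if len(pts) < 2:
        raise RSMLError(f"{where}/polyline: fewer than 2 points")
    return np.asarray(pts, dtype=float)


def _parse_root(el: etree._Element, where: str, depth: int, parent: Root | None):
    if depth > 2:
        raise RSMLError(
            f"{where}: root nesting depth {depth} unsupported (orders 1-2 only)"
        )
    geom = el.find("geometry")
    if geom is None:
        raise RSMLError(f"{where}: root without geometry")
    points = _parse_polyline(geom, where)
    if depth == 1:
        root = Root(order=1, points=points)
    else:
        base = points[0]
        # snap the attachment onto the parent polyline
        d = point_to_polyline_distance(base, parent.points)
        attach = base if d <= 1.0 else project_to_polyline(base, parent.points)
        root = Root(order=2, points=points, parent=parent, attachment=attach)
    out = [root]
    for i, child in enumerate(el.findall("root"), start=1):
        out.extend(_parse_root(child, f"{where}/root[{i}]", depth + 1, root))
    return out


def read_rsml(source: str | Path | bytes) -> RootSystem:
    """Parse an RSML document into a :class:`RootSystem`.

    Accepts a filesystem path or raw XML bytes.  Roots nested deeper than
    two levels raise :class:`RSMLError`, as do missing geometries.
    """
    try:
        if isinstance(source, bytes):
            rsml = etree.fromstring(source)
        else:
            rsml = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise RSMLError(f"malformed XML: {exc}") from exc

    rs = RootSystem()
    scene = rsml.find("scene")
    if scene is None:
        return rs
    for pi, pl in enumerate(scene.findall("plant"), start=1):
        where = f"scene/plant[{pi}]"
        seed_el = pl.find("properties/seed")
        roots: list[Root] = []
        for ri, rel in enumerate(pl.findall("root"), start=1):
            roots.extend(_parse_root(rel, f"{where}/root[{ri}]", 1, None))
        if seed_el is not None:
            seed = np.array([float(seed_el.get("x")), float(seed_el.get("y"))])
        else:
            order1 = [r for r in roots if r.order == 1]
            if order1:
                seed = order1[0].points[0].copy()
            else:
                raise RSMLError(f"{where}: no seed property and no order-1 root")
        rs.plants.append(Plant(seed=seed, roots=roots))
    return rs


def write_masks(
    maps: ClassMaps, paths: dict[str, str | Path]
) -> dict[str, Path]:
    """Export binary order-1/order-2 masks as 8-bit PNGs.

    ``paths`` maps channel names (``order1``, ``order2``; optionally
    ``background``) to output file paths.  Values >= 0.5 are written as 255.
    """
    written = {}
    for channel, path in paths.items():
        arr = getattr(maps, channel)
        img = ((np.asarray(arr) >= 0.5) * 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(str(path))
        written[channel] = Path(path)
    return written
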