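# Annotation file schema

One image of one plant is described by a pod-annotation XML and a skeleton
JSON sharing the same file stem (`<accession>_<replicate>_<side>`).
All coordinates are pixels, origin top-left, y downward.

## Pod annotation XML (VOC dialect)

```xml
<annotation>
  <filename>PI001_r1_front</filename>
  <accession>PI001</accession>
  <replicate>r1</replicate>
  <side>front</side>            <!-- front | back -->
  <object>
    <name>pod</name>            <!-- one per pod -->
    <bndbox>
      <xmin>497.0</xmin><ymin>312.0</ymin>
      <xmax>503.0</xmax><ymax>318.0</ymax>
    </bndbox>
  </object>
  <object><name>top</name>    <bndbox>...</bndbox></object>
  <object><name>bottom</name> <bndbox>...</bndbox></object>
  <object>
    <name>scale</name>          <!-- segment of known physical length -->
    <bndbox><xmin>10</xmin><ymin>5</ymin><xmax>110</xmax><ymax>5</ymax></bndbox>
    <length_cm>10.0</length_cm>
  </object>
</annotation>
```

* Pod centers are bounding-box midpoints.
* Exactly one `top` and one `bottom` object are required; `bottom` marks
  the soil-line cut from which heights are measured.
* px_per_cm = (longer side of the scale box) / `length_cm`. A scale
  object is required unless a `--scale-override` is supplied.
* Unknown object names are ignored with a warning.

## Skeleton JSON

```json
{
 "image_id": "PI001_r1_front",
 "accession": "PI001",
 "replicate": "r1",
 "side": "front",
 "px_per_cm": 10.0,
 "base": [520.0, 770.0],
 "polylines": [
  {"role": "main",    "points": [[520.0, 770.0], [520.0, 715.0], ...]},
  {"role": "primary", "points": [[520.0, 715.0], [678.0, 490.0], ...]}
 ]
}
```

* Exactly one polyline has role `main`; its end nearest `base` becomes the
  base vertex.
* Each `primary` polyline starts at (or within the snap tolerance of, by
  default 2 px) a vertex of the main polyline.
* `px_per_cm` is optional; the paired XML's scale object takes precedence
  during a pipeline run.

## Genotypes

Standard VCF v4.x, one biallelic record per marker, `GT` format field:
`0/0` reference, `1/1` non-reference, `0/1` heterozygous, `./.` missing.
Sample names must match accession ids. Multi-allelic records are
rejected.
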