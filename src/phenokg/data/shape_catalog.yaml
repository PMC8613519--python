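# Default content-standard catalog: one shape template per descriptive
# named-graph category.  Each template lists the roles a graph of that
# category must bind and, where applicable, a constraint on the role's
# value (a datatype, or the root of the term subtree the value must fall
# under).  Templates are data, not code: domains extend the content
# standard by editing or replacing this file.
templates:
  - category: EX:parthood
    roles: [whole, part]
  - category: EX:instantiation
    roles: [instance, class]
  - category: EX:shape
    roles: [bearer, quality]
    constraints:
      quality: {under: "EX:shape-quality"}
  - category: EX:color
    roles: [bearer, quality]
    constraints:
      quality: {under: "PATO:0000020"}
  - category: EX:weight
    roles: [bearer, value, unit]
    constraints:
      value: {datatype: decimal}
      unit: {under: "EX:unit"}
  - category: EX:length
    roles: [bearer, value, unit]
    constraints:
      value: {datatype: decimal}
      unit: {under: "EX:unit"}
  - category: EX:volume
    roles: [bearer, value, unit]
    constraints:
      value: {datatype: decimal}
      unit: {under: "EX:unit"}
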