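"""Edit a converted model: add a molecule diffusing in the cytosol and a
transport reaction exporting it across the plasma membrane.

This is the minimal biochemistry that turns a bare geometry into a runnable
reaction–diffusion model: a species per compartment, a diffusion coefficient,
a rate constant, and one membrane-local transport reaction with mass-action
kinetics.  The exported document can be handed to any spatial-SBML-capable
simulator.
"""

from pathlib import Path

from voxsbml import (
    add_reaction,
    add_spatial_parameter,
    add_species,
    export_sbml,
    fixtures,
    masks_to_model,
)

model = masks_to_model(fixtures.nested_spheres(), name="transport_demo").model

add_species(model, "A_cyt", "Cyt", 1.0)   # 1.0 concentration unit in the cytosol
add_species(model, "A_ec", "EC", 0.0)     # initially absent outside
add_spatial_parameter(model, "D_A", 1e-12, role="diffusion", species="A_cyt")
add_spatial_parameter(model, "k_export", 0.3)
add_reaction(
    model, "export_A", ["A_cyt"], ["A_ec"], "k_export * A_cyt",
    membrane_local=True, compartment="PM",
)

print("species:   ", [(s.id, s.compartment, s.initial_concentration) for s in model.species])
print("parameters:", [(p.id, p.role) for p in model.parameters])
print("reaction:  ", model.reactions[0].id, "=", model.reactions[0].rate_expression,
      "(on", model.reactions[0].compartment + ")")

out = Path("transport_demo.xml")
export_sbml(model, out)
print(f"wrote {out}")
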