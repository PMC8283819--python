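"""Single-process simulation of the multi-agent control-dispatch layer.

A coordinator agent receives a control plan (which device classes to run,
how many, when), turns it into a task list, assigns idle equipment agents
FIFO by start time, asks the flow-control agent to split the influent flow
across the assigned devices in proportion to their capability levels, and
processes completion/failure feedback on an event queue.  Every message and
status transition is appended to a trace, mirroring the
plan -> task list -> equipment -> feedback information flow.

Policies the block diagrams leave open are fixed here: FIFO assignment with
ties broken by plan order then device id, proportional flow split, and a
single retry for a failed task before it is declared unassignable.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TaskStatus",
    "DeviceStatus",
    "ControlTask",
    "DeviceRecord",
    "FlowAllocation",
    "Event",
    "plan_to_tasks",
    "dispatch",
    "DispatchSimulator",
    "random_scenario",
]

logger = logging.getLogger(__name__)

FLOW_TOL = 1e-9


class TaskStatus(str, Enum):
    PENDING = "pending"
    RUNNING = "running"
    DONE = "done"
    FAILED = "failed"


_FORWARD = {
    TaskStatus.PENDING: {TaskStatus.RUNNING, TaskStatus.FAILED},
    TaskStatus.RUNNING: {TaskStatus.DONE, TaskStatus.FAILED},
    TaskStatus.DONE: set(),
    TaskStatus.FAILED: {TaskStatus.PENDING},  # one retry re-queues the task
}


class DeviceStatus(str, Enum):
    IDLE = "idle"
    BUSY = "busy"
    FAILED = "failed"


@dataclass
class ControlTask:
    """One line of the control task list."""

    task_id: str
    device_class: str
    count: int
    start_time: float
    status: TaskStatus = TaskStatus.PENDING
    device_ids: list[str] = field(default_factory=list)
    retries: int = 0

    def advance(self, new: TaskStatus) -> None:
        if new not in _FORWARD[self.status]:
            raise ValueError(f"illegal task transition {self.status} -> {new}")
        self.status = new


@dataclass
class DeviceRecord:
    """Equipment-agent bookkeeping: capability, unit, history, depreciation."""

    device_id: str
    device_class: str
    capability: float = 1.0
    subordinate_unit: str = ""
    status: DeviceStatus = DeviceStatus.IDLE
    history: list[dict] = field(default_factory=list)
    depreciation: float = 0.0

    def log(self, clock: float, event: str, **info) -> None:
        self.history.append({"t": clock, "event": event, **info})

    def wear(self, amount: float = 1.0) -> None:
        if amount < 0:
            raise ValueError("depreciation only accumulates")
        self.depreciation += amount


@dataclass(frozen=True)
class FlowAllocation:
    """Split of the influent flow across assigned devices (m^3/h)."""

    total: float
    per_device: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_device.values()):
            raise ValueError("allocations must be nonnegative")
        if self.per_device and abs(sum(self.per_device.values()) - self.total) > FLOW_TOL:
            raise ValueError("allocations must sum to the total flow")


def plan_to_tasks(plan: Sequence[tuple[str, int, float]]) -> list[ControlTask]:
    """Control plan lines (device class, quantity, start time) -> task list.

    Task ids are assigned deterministically in plan order (T000, T001, ...).
    """
    tasks = []
    for i, (device_class, quantity, start_time) in enumerate(plan):
        if quantity < 1:
            raise ValueError(f"plan line {i}: quantity must be >= 1")
        if start_time < 0:
            raise ValueError(f"plan line {i}: start time must be >= 0")
        tasks.append(
            ControlTask(
                task_id=f"T{i:03d}",
                device_class=str(device_class),
                count=int(quantity),
                start_time=float(start_time),
            )
        )
    return tasks


def allocate_flow(total: float, devices: Sequence[DeviceRecord]) -> FlowAllocation:
    """Proportional-to-capability split of the total flow."""
    if total < 0:
        raise ValueError("flow must be nonnegative")
    if not devices:
        return FlowAllocation(total=0.0, per_device={})
    caps = np.array([d.capability for d in devices], dtype=float)
    if caps.sum() <= 0:
        shares = np.full(len(devices), total / len(devices))
    else:
        shares = total * caps / caps.sum()
    # absorb rounding in the last share so the sum is exact
    shares[-1] = total - shares[:-1].sum()
    return FlowAllocation(
        total=total, per_device={d.device_id: float(s) for d, s in zip(devices, shares)}
    )


@dataclass
class DispatchResult:
    assigned: list[ControlTask]
    unassignable: list[ControlTask]
    allocation: FlowAllocation
    trace: list[dict]


def dispatch(
    tasks: Sequence[ControlTask],
    devices: Sequence[DeviceRecord],
    flow_total: float,
    clock: float = 0.0,
    trace: list[dict] | None = None,
) -> DispatchResult:
    """Assign tasks to idle devices and split the flow among them.

    Tasks are served FIFO by start time (ties by task id, i.e. plan order);
    each task needs ``count`` idle devices of its class, taken in device-id
    order.  Tasks that cannot be staffed are listed as unassignable.  The
    flow is split over all devices assigned in this round.
    """
    trace = trace if trace is not None else []
    known_classes = {d.device_class for d in devices}
    pool = {
        cls: sorted(
            (d for d in devices if d.device_class == cls and d.status == DeviceStatus.IDLE),
            key=lambda d: d.device_id,
        )
        for cls in known_classes
    }
    assigned: list[ControlTask] = []
    unassignable: list[ControlTask] = []
    busy: list[DeviceRecord] = []

    for task in sorted(tasks, key=lambda tk: (tk.start_time, tk.task_id)):
        trace.append({"t": clock, "msg": "task_received", "task": task.task_id})
        if task.device_class not in known_classes:
            raise ValueError(f"unknown device class {task.device_class!r} in {task.task_id}")
        idle = pool[task.device_class]
        if len(idle) < task.count:
            unassignable.append(task)
            trace.append(
                {"t": clock, "msg": "task_unassignable", "task": task.task_id,
                 "needed": task.count, "idle": len(idle)}
            )
            continue
        chosen, pool[task.device_class] = idle[: task.count], idle[task.count:]
        task.device_ids = [d.device_id for d in chosen]
        task.advance(TaskStatus.RUNNING)
        for dev in chosen:
            dev.status = DeviceStatus.BUSY
            dev.log(clock, "assigned", task=task.task_id)
            dev.wear()
            busy.append(dev)
        assigned.append(task)
        trace.append(
            {"t": clock, "msg": "task_started", "task": task.task_id,
             "devices": list(task.device_ids)}
        )

    allocation = allocate_flow(flow_total if busy else 0.0, busy)
    trace.append(
        {"t": clock, "msg": "flow_allocated", "total": allocation.total,
         "per_device": dict(allocation.per_device)}
    )
    return DispatchResult(
        assigned=assigned, unassignable=unassignable, allocation=allocation, trace=trace
    )


@dataclass(frozen=True, order=True)
class Event:
    """Time-stamped message on the coordinator's queue."""

    time: float
    seq: int
    kind: str = field(compare=False)  # "complete" | "fail" | "status"
    task_id: str = field(compare=False, default="")
    info: tuple = field(compare=False, default=())


class DispatchSimulator:
    """Discrete-event loop over tasks, devices and feedback messages."""

    def __init__(
        self,
        tasks: Iterable[ControlTask],
        devices: Iterable[DeviceRecord],
        flow_total: float,
    ) -> None:
        self.tasks = {t.task_id: t for t in tasks}
        self.devices = {d.device_id: d for d in devices}
        self.flow_total = float(flow_total)
        self.clock = 0.0
        self.trace: list[dict] = []
        self._queue: list[Event] = []
        self._seq = itertools.count()
        self.unassignable: list[ControlTask] = []
        self.allocation = FlowAllocation(total=0.0, per_device={})

    def schedule(self, time: float, kind: str, task_id: str = "", info: tuple = ()) -> None:
        heapq.heappush(self._queue, Event(time, next(self._seq), kind, task_id, info))

    def run_dispatch(self) -> DispatchResult:
        pending = [t for t in self.tasks.values() if t.status == TaskStatus.PENDING]
        result = dispatch(
            pending, list(self.devices.values()), self.flow_total, self.clock, self.trace
        )
        for t in result.unassignable:
            if t not in self.unassignable:
                self.unassignable.append(t)
        self.allocation = result.allocation
        return result

    def _release(self, task: ControlTask) -> None:
        for dev_id in task.device_ids:
            dev = self.devices[dev_id]
            if dev.status == DeviceStatus.BUSY:
                dev.status = DeviceStatus.IDLE
                dev.log(self.clock, "released", task=task.task_id)

    def step(self) -> None:
        """Process every event scheduled at the next event time."""
        if not self._queue:
            return
        self.clock = self._queue[0].time
        while self._queue and self._queue[0].time == self.clock:
            ev = heapq.heappop(self._queue)
            self._handle(ev)

    def run(self) -> None:
        while self._queue:
            self.step()

    def _handle(self, ev: Event) -> None:
        task = self.tasks.get(ev.task_id)
        if ev.kind in ("complete", "fail") and task is None:
            logger.warning("event for unknown task %r skipped", ev.task_id)
            self.trace.append({"t": self.clock, "msg": "unknown_task_event", "task": ev.task_id})
            return
        if ev.kind == "complete":
            if task.status != TaskStatus.RUNNING:
                self.trace.append(
                    {"t": self.clock, "msg": "stale_completion", "task": task.task_id}
                )
                return
            task.advance(TaskStatus.DONE)
            self._release(task)
            self.trace.append({"t": self.clock, "msg": "task_done", "task": task.task_id})
        elif ev.kind == "fail":
            if task.status != TaskStatus.RUNNING:
                self.trace.append({"t": self.clock, "msg": "stale_failure", "task": task.task_id})
                return
            task.advance(TaskStatus.FAILED)
            self._release(task)
            self.trace.append({"t": self.clock, "msg": "task_failed", "task": task.task_id})
            if task.retries < 1:
                task.retries += 1
                task.advance(TaskStatus.PENDING)
                task.device_ids = []
                self.trace.append({"t": self.clock, "msg": "task_requeued", "task": task.task_id})
                self.run_dispatch()
            else:
                if task not in self.unassignable:
                    self.unassignable.append(task)
                self.trace.append(
                    {"t": self.clock, "msg": "task_abandoned", "task": task.task_id}
                )
        elif ev.kind == "status":
            dev = self.devices.get(ev.task_id)  # device-status events carry a device id
            if dev is None:
                logger.warning("status event for unknown device %r skipped", ev.task_id)
                self.trace.append(
                    {"t": self.clock, "msg": "unknown_device_event", "device": ev.task_id}
                )
                return
            dev.log(self.clock, "status_update", info=ev.info)
            self.trace.append(
                {"t": self.clock, "msg": "device_status", "device": dev.device_id,
                 "info": list(ev.info)}
            )
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")


def random_scenario(rng: np.random.Generator) -> tuple[list, list[DeviceRecord], float]:
    """Random plan / device fleet / flow total for conservation testing."""
    classes = ["blower", "pump", "valve"][: rng.integers(1, 4)]
    devices = [
        DeviceRecord(
            device_id=f"D{i:02d}",
            device_class=str(rng.choice(classes)),
            capability=float(rng.integers(1, 5)),
        )
        for i in range(rng.integers(1, 9))
    ]
    present = sorted({d.device_class for d in devices})
    plan = [
        (str(rng.choice(present)), int(rng.integers(1, 4)), float(rng.integers(0, 5)))
        for _ in range(rng.integers(1, 7))
    ]
    return plan, devices, float(rng.uniform(10, 200))
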